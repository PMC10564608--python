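"""Synthetic cohort generation: participants, recall sessions and paired
tool measurements with controlled agreement structure.

This is test scaffolding for the whole pipeline — it does not model real
Brazilian diets.  Paired Nova shares are drawn from an additive-log-ratio
(ALR) normal model so noisy share vectors stay on the simplex: each
participant has a latent 3-dimensional ALR coordinate (groups 2..4 against
group 1) drawn around the population mean with between-subject spread, and
each tool observes it with independent within-tool noise (plus an optional
tool bias).  Because both noise layers live on the ALR scale, the implied
intraclass correlation per coordinate is the closed-form variance ratio
sigma_b^2 / (sigma_b^2 + sigma_w^2).

Default cohort conditions mirror a nationwide two-tool agreement study: 186
participants sampled to the Brazilian adult demographic mix, a ~12 %
fraction of participants (23/186) leaving type/source/preparation fields
blank, population mean shares near 52.6/11.9/14.7/20.9 % of energy for the
four Nova groups, and ALR noise chosen so the implied per-coordinate ICC is
about 0.72 — inside the moderate-to-good range the two tools exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .database import FoodDatabase
from .errors import ContractError
from .processing import DistributionTable, PopulationDistribution
from .questions import (
    RecallSession,
    REFINER_QTYPES,
    finalize_session,
    next_questions,
    record_answer,
)

_DEFAULT_DEMOGRAPHICS = {
    "sex": {"female": 0.55, "male": 0.45},
    "age_band": {"18-34": 0.38, "35-54": 0.40, "55+": 0.22},
    "region": {"southeast_northeast": 0.61, "other": 0.39},
    "education": {"up_to_primary": 0.049, "secondary": 0.462, "higher": 0.489},
    "bmi_category": {"not_overweight": 0.46, "overweight": 0.30, "obese": 0.24},
}


@dataclass
class CohortSpec:
    """Conditions under which a synthetic cohort is generated."""

    n_participants: int = 186
    seed: int = 2020
    #: category -> {level: target proportion}; each must sum to 1
    demographics: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_DEMOGRAPHICS.items()})
    #: fraction of participants who omit imputable refiner answers
    missingness_rate: float = 23 / 186
    #: population mean Nova shares (% of energy, groups 1..4); renormalized
    mean_shares: tuple[float, float, float, float] = (52.6, 11.9, 14.7, 20.9)
    #: between-subject SD of the latent ALR coordinates
    between_sd: float = 0.8
    #: within-subject (tool) SD on the ALR scale
    within_sd: float = 0.5
    #: additive ALR bias of tool B (groups 2..4 against group 1)
    tool_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: probability a key question is answered 'yes' in simulated sessions
    p_key_yes: float = 0.35

    def __post_init__(self):
        if not 0 <= self.missingness_rate <= 1:
            raise ContractError("missingness_rate must lie in [0, 1]")
        if self.between_sd < 0 or self.within_sd < 0:
            raise ContractError("SDs must be non-negative")
        if min(self.mean_shares) <= 0:
            raise ContractError("mean shares must be positive")
        for category, levels in self.demographics.items():
            total = sum(levels.values())
            if abs(total - 1.0) > 1e-6:
                raise ContractError(
                    f"demographic proportions for {category!r} sum to {total}")

    def implied_icc(self) -> float:
        """Closed-form per-ALR-coordinate ICC implied by the noise spec."""
        b2, w2 = self.between_sd ** 2, self.within_sd ** 2
        if b2 + w2 == 0:
            raise ContractError("degenerate variance spec: no variation at all")
        return b2 / (b2 + w2)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("mean_shares", "tool_bias"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# ALR transform
# ---------------------------------------------------------------------------


def alr(shares: np.ndarray) -> np.ndarray:
    """Additive log-ratio coordinates of share vectors (last axis, group 1
    as reference): log(s_g / s_1) for g = 2..4."""
    shares = np.asarray(shares, dtype=float)
    return np.log(shares[..., 1:] / shares[..., :1])


def inv_alr(coords: np.ndarray) -> np.ndarray:
    """Inverse ALR: coordinates back to share vectors summing to 1."""
    coords = np.asarray(coords, dtype=float)
    expanded = np.concatenate(
        [np.zeros(coords.shape[:-1] + (1,)), coords], axis=-1)
    expanded = np.exp(expanded - expanded.max(axis=-1, keepdims=True))
    return expanded / expanded.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# participants + paired shares
# ---------------------------------------------------------------------------


def simulate_participants(spec: CohortSpec,
                          rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Participant table with seeded demographic labels drawn from the
    cohort's target proportions."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_participants
    data = {"participant_id": [f"p{i:04d}" for i in range(n)]}
    for category, levels in spec.demographics.items():
        names = list(levels)
        probs = np.array([levels[name] for name in names], dtype=float)
        probs = probs / probs.sum()
        data[category] = rng.choice(names, size=n, p=probs)
    return pd.DataFrame(data)


def simulate_paired_shares(
    spec: CohortSpec,
    rng: Optional[np.random.Generator] = None,
    tools: tuple[str, str] = ("tool_a", "tool_b"),
) -> pd.DataFrame:
    """Paired Nova-share table (long format) for two tools observing the
    same latent diet with independent ALR noise."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_participants
    mean = np.asarray(spec.mean_shares, dtype=float)
    mu = alr(mean / mean.sum())
    latent = mu + spec.between_sd * rng.standard_normal((n, 3))
    obs_a = latent + spec.within_sd * rng.standard_normal((n, 3))
    obs_b = (latent + np.asarray(spec.tool_bias, dtype=float)
             + spec.within_sd * rng.standard_normal((n, 3)))
    rows = []
    for tool, obs in zip(tools, (obs_a, obs_b)):
        shares = inv_alr(obs) * 100.0
        for i in range(n):
            for g in range(4):
                rows.append({"participant_id": f"p{i:04d}", "tool": tool,
                             "nova_group": g + 1,
                             "share_pct": float(shares[i, g])})
    return pd.DataFrame(rows, columns=["participant_id", "tool", "nova_group",
                                       "share_pct"])


# ---------------------------------------------------------------------------
# sessions + population distributions
# ---------------------------------------------------------------------------


def simulate_population_distributions(
    db: FoodDatabase,
    seed: int = 0,
    concentration: float = 2.0,
) -> DistributionTable:
    """A population answer distribution (Dirichlet draw) for every imputable
    refiner question of the database."""
    rng = np.random.default_rng(seed)
    dists = []
    for node in db.graph.ordered():
        if node.qtype not in REFINER_QTYPES or not node.impute_field:
            continue
        subject = node.subject
        if subject is None:
            continue
        shares = rng.dirichlet(np.full(len(node.options), concentration))
        shares = shares / shares.sum()
        pairs = [(o.option_id, float(s)) for o, s in zip(node.options, shares)]
        # exact unit sum for the contract check
        pairs[-1] = (pairs[-1][0], 1.0 - sum(s for _, s in pairs[:-1]))
        dists.append(PopulationDistribution(
            item_id=subject, field=node.impute_field, shares=tuple(pairs)))
    return DistributionTable(dists)


def simulate_sessions(
    spec: CohortSpec,
    db: FoodDatabase,
    rng: Optional[np.random.Generator] = None,
) -> list[RecallSession]:
    """Seeded random traversals of the question graph.

    A ``missingness_rate`` fraction of participants skip every triggered
    preparation/detail (imputable) question; everyone answers restriction,
    usual-intake and supplement questions.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    sessions = []
    for i in range(spec.n_participants):
        misser = rng.random() < spec.missingness_rate
        session = RecallSession(participant_id=f"p{i:04d}",
                                recall_date="2020-10-01")
        pending = next_questions(db.graph, session)
        while pending:
            node = pending[0]
            if node.qtype == "key":
                yes = rng.random() < spec.p_key_yes
                record_answer(db.graph, session, node.question_id,
                              ("yes" if yes else "no",))
            elif node.qtype == "type_amount":
                n_pick = 1 + int(rng.random() < 0.25 and len(node.options) > 1)
                picks = rng.choice(len(node.options), size=min(n_pick, len(node.options)),
                                   replace=False)
                option_ids = tuple(node.options[j].option_id for j in sorted(picks))
                amounts = {oid: float(rng.integers(1, 4)) for oid in option_ids}
                record_answer(db.graph, session, node.question_id, option_ids,
                              amounts)
            elif node.qtype in REFINER_QTYPES:
                if misser:
                    record_answer(db.graph, session, node.question_id, skipped=True)
                else:
                    j = int(rng.integers(0, len(node.options)))
                    record_answer(db.graph, session, node.question_id,
                                  (node.options[j].option_id,))
            elif node.qtype == "added_item":
                with_item = [o for o in node.options if o.item_id is not None]
                without = [o for o in node.options if o.item_id is None]
                if with_item and rng.random() < 0.5:
                    o = with_item[int(rng.integers(0, len(with_item)))]
                    record_answer(db.graph, session, node.question_id,
                                  (o.option_id,), {o.option_id: float(rng.integers(1, 3))})
                elif without:
                    record_answer(db.graph, session, node.question_id,
                                  (without[0].option_id,))
                else:
                    record_answer(db.graph, session, node.question_id, skipped=True)
            else:  # restriction / usual_intake / supplement
                j = int(rng.integers(0, len(node.options)))
                record_answer(db.graph, session, node.question_id,
                              (node.options[j].option_id,))
            pending = next_questions(db.graph, session)
        finalize_session(db.graph, session)
        sessions.append(session)
    return sessions
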