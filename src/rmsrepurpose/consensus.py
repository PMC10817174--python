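"""Consensus candidate selection and report summaries.

Combines the two models' external predictions for one test cell line
into ranked shortlists: drugs both models call resistant (or sensitive)
are ranked by the AE-NN model's cross-validated AUC and the top k are
kept. An optional extension step appends additional drugs filtered by
annotation (FDA approval, assay availability), again ranked by AUC.
Group summaries report mean +/- SD of AUC and F1, rounded half-up to
two decimals as in the report tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .aenn import RESISTANT, SENSITIVE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DrugAnnotation:
    drug_id: str
    fda_approved: bool = False
    available_for_assay: bool = True


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GroupSummary:
    """Mean and sample SD of a group's AUC and F1 values.

    Unrounded values are kept; ``rounded()`` applies the two-decimal
    half-up convention used for reporting.
    """

    mean_auc: float
    sd_auc: float
    mean_f1: float
    sd_f1: float

    def rounded(self) -> tuple[float, float, float, float]:
        return tuple(_round2(v) for v in (self.mean_auc, self.sd_auc, self.mean_f1, self.sd_f1))


def group_summary(rows: list[tuple[float, float]]) -> GroupSummary:
    """Summarize (auc, f1) rows; SD is the sample SD (0 for a singleton)."""
    if not rows:
        raise ValueError("group_summary needs at least one row")
    arr = np.asarray(rows, dtype=float)
    sd = arr.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(2)
    return GroupSummary(
        mean_auc=float(arr[:, 0].mean()),
        sd_auc=float(sd[0]),
        mean_f1=float(arr[:, 1].mean()),
        sd_f1=float(sd[1]),
    )


@dataclass(frozen=True)
class CandidateRow:
    drug_id: str
    auc: float
    f1: float
    aenn_call: str
    superfelt_call: str
    extended: bool = False


@dataclass
class CandidateReport:
    """Ranked resistant/sensitive shortlists for one test cell line."""

    cell_id: str
    resistant_candidates: list[CandidateRow] = field(default_factory=list)
    sensitive_candidates: list[CandidateRow] = field(default_factory=list)
    group_summaries: dict[str, GroupSummary] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, cands in (
            ("resistant", self.resistant_candidates),
            ("sensitive", self.sensitive_candidates),
        ):
            for c in cands:
                rows.append(
                    {
                        "cell_line": self.cell_id,
                        "group": group,
                        "drug": c.drug_id,
                        "AUC": _round2(c.auc),
                        "F1": _round2(c.f1),
                        "aenn_call": c.aenn_call,
                        "superfelt_call": c.superfelt_call,
                        "extended": c.extended,
                    }
                )
            if cands and group in self.group_summaries:
                m_auc, sd_auc, m_f1, sd_f1 = self.group_summaries[group].rounded()
                rows.append(
                    {
                        "cell_line": self.cell_id,
                        "group": group,
                        "drug": "Avg",
                        "AUC": m_auc,
                        "F1": m_f1,
                        "aenn_call": f"±{sd_auc}",
                        "superfelt_call": f"±{sd_f1}",
                        "extended": False,
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _ranked(eligible: pd.DataFrame) -> pd.DataFrame:
    # descending AUC; alphabetical drug id breaks ties for determinism
    return eligible.sort_values(
        ["auc", "drug"], ascending=[False, True], kind="stable"
    )


def select_candidates(
    aenn_calls: pd.Series,
    superfelt_calls: pd.Series,
    cv_metrics: pd.DataFrame,
    k: int = 5,
    require_consistency: str = "both",
    annotations: list[DrugAnnotation] | None = None,
    extend_m: int = 0,
    cell_id: str = "",
) -> CandidateReport:
    """Build ranked shortlists of resistant and sensitive candidates.

    Parameters
    ----------
    aenn_calls, superfelt_calls : Series
        Per-drug calls ('resistant'/'sensitive') of each model for one
        test cell line; joined on the shared drug ids.
    cv_metrics : DataFrame
        Per-drug training metrics with columns ``auc`` and ``f1``.
    k : int
        Shortlist length per group.
    require_consistency : {'both', 'resistant_only'}
        Whether cross-model agreement is required for both groups or
        only the resistant one.
    annotations, extend_m :
        When given, up to ``extend_m`` extra drugs per group are
        appended from the assay-available annotated drugs with the
        matching AE-NN call, FDA-approved ones first, then by AUC.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if require_consistency not in ("both", "resistant_only"):
        raise ValueError("require_consistency must be 'both' or 'resistant_only'")
    shared = aenn_calls.index.intersection(superfelt_calls.index).intersection(
        cv_metrics.index
    )
    dropped = len(set(aenn_calls.index) | set(superfelt_calls.index)) - len(shared)
    if dropped:
        logger.info("select_candidates: dropped %d drugs outside the shared universe", dropped)
    table = pd.DataFrame(
        {
            "drug": shared,
            "aenn": aenn_calls.loc[shared].to_numpy(),
            "superfelt": superfelt_calls.loc[shared].to_numpy(),
            "auc": cv_metrics.loc[shared, "auc"].to_numpy(),
            "f1": cv_metrics.loc[shared, "f1"].to_numpy(),
        }
    )
    ann = {a.drug_id: a for a in annotations or []}

    report = CandidateReport(cell_id=cell_id)
    for group, call in ((RESISTANT, RESISTANT), (SENSITIVE, SENSITIVE)):
        need_consistency = require_consistency == "both" or group == RESISTANT
        eligible = table[table["aenn"] == call]
        if need_consistency:
            eligible = eligible[eligible["superfelt"] == call]
        if eligible.empty:
            logger.warning("select_candidates: no eligible %s drugs", group)
        shortlist = _ranked(eligible).head(k)
        rows = [
            CandidateRow(r.drug, r.auc, r.f1, r.aenn, r.superfelt)
            for r in shortlist.itertuples()
        ]
        if ann and extend_m > 0:
            chosen = {c.drug_id for c in rows}
            pool = table[
                (table["aenn"] == call)
                & ~table["drug"].isin(chosen)
                & table["drug"].map(
                    lambda d: d in ann and ann[d].available_for_assay
                )
            ].copy()
            pool["fda"] = pool["drug"].map(lambda d: ann[d].fda_approved)
            pool = pool.sort_values(
                ["fda", "auc", "drug"], ascending=[False, False, True], kind="stable"
            ).head(extend_m)
            rows += [
                CandidateRow(r.drug, r.auc, r.f1, r.aenn, r.superfelt, extended=True)
                for r in pool.itertuples()
            ]
        if group == RESISTANT:
            report.resistant_candidates = rows
        else:
            report.sensitive_candidates = rows
        if rows:
            report.group_summaries[group] = group_summary(
                [(c.auc, c.f1) for c in rows]
            )
    return report
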