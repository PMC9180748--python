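"""Differential-expression calling on label-free quantitation tables.

A protein is called differentially expressed (DEP) when it passes, in
order: (1) ≥ ``min_unique_peptides`` unique peptides used for
quantitation; (2) identification FDR < ``max_id_fdr``; (3) fold-change
magnitude ≥ ``min_fc`` between averaged, normalized intensities of the
two compared groups; (4) one-way ANOVA p ≤ ``max_p``.

The identification-FDR gate is a search-engine confidence filter
carried in the input table, not a multiple-testing correction of the
ANOVA p-values — the p ≤ 0.05 threshold is applied to raw p-values,
with an optional Benjamini–Hochberg adjustment available for
sensitivity analysis (``bh_correct``).

Fold changes are ratios of arithmetic means of normalized linear
intensities; the magnitude max(r, 1/r) is direction-free, so a
1.5-fold decrease passes a 1.5-fold gate exactly like an increase.
ANOVA runs on linear intensities by default (matching the fold-change
convention) with a log2 option.  Proteins lacking two observed
replicates in any compared group are untestable: they are excluded
from calling and reported with a reason, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lysoquant.quantio import QuantMatrix


@dataclass(frozen=True)
class DEPParams:
    """Filter thresholds for DEP calling.

    ``min_fc`` defaults to 1.5 (cell-line comparisons); use 1.3 for
    mouse-brain datasets.
    """

    min_unique_peptides: int = 2
    max_id_fdr: float = 0.01
    min_fc: float = 1.5
    max_p: float = 0.05
    log_scale: bool = False  # ANOVA on log2 intensities instead of linear
    bh_correct: bool = False  # BH-adjust ANOVA p-values before the p gate

    def __post_init__(self) -> None:
        if self.min_fc < 1:
            raise ValueError(f"min_fc must be ≥ 1, got {self.min_fc}")
        for name in ("max_p", "max_id_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class DEPRecord:
    """Per-protein differential-expression outcome with per-filter flags."""

    accession: str
    gene_symbol: str
    fc_signed: float
    fc_magnitude: float
    p_value: float
    pass_peptides: bool
    pass_fdr: bool
    pass_fc: bool
    pass_p: bool
    is_dep: bool
    testable: bool = True
    reason: str = ""


def normalize_intensities(
    matrix: QuantMatrix, method: str = "median-scale"
) -> QuantMatrix:
    """Equalize per-sample medians over the shared observed proteins.

    Under ``median-scale`` every sample is rescaled so its median over
    proteins observed in all samples equals the grand median of those
    proteins.  ``none`` returns the matrix unchanged.  Missing cells
    stay missing.
    """
    if method == "none":
        return matrix
    if method != "median-scale":
        raise ValueError(f"unknown normalization method {method!r}")
    vals = matrix.intensities
    n_obs = vals.notna().sum(axis=0)
    if (n_obs == 0).any():
        empty = n_obs[n_obs == 0].index.tolist()
        raise ValueError(f"samples with no observed intensities: {empty}")
    complete = vals.dropna(axis=0)
    if complete.empty:
        raise ValueError("no protein observed in every sample; cannot median-scale")
    sample_medians = complete.median(axis=0)
    grand = float(np.median(complete.to_numpy()))
    scaled = vals * (grand / sample_medians)
    return QuantMatrix(scaled, dict(matrix.group_of))


def fold_change(
    case_values: Sequence[float], control_values: Sequence[float]
) -> tuple[float, float]:
    """Signed and magnitude fold change of averaged intensities.

    Returns ``(mean(case)/mean(control), max(r, 1/r))``.
    """
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    case = case[~np.isnan(case)]
    ctrl = ctrl[~np.isnan(ctrl)]
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("fold change needs ≥1 observed value on each side")
    m_case, m_ctrl = case.mean(), ctrl.mean()
    if m_case <= 0 or m_ctrl <= 0:
        raise ValueError(f"non-positive group mean ({m_case}, {m_ctrl})")
    r = m_case / m_ctrl
    return r, max(r, 1.0 / r)


def anova_p(groups: Sequence[Sequence[float]]) -> float:
    """One-way fixed-effects ANOVA p-value across ≥2 groups.

    Each group needs ≥2 observed values.  When all values are
    identical the F statistic is 0 and p = 1.
    """
    cleaned = []
    for g in groups:
        a = np.asarray(g, dtype=float)
        a = a[~np.isnan(a)]
        if a.size < 2:
            raise ValueError("every group needs ≥2 observed values for ANOVA")
        cleaned.append(a)
    if len(cleaned) < 2:
        raise ValueError("ANOVA needs ≥2 groups")
    allv = np.concatenate(cleaned)
    if np.allclose(allv, allv[0]):
        return 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*cleaned)
    if np.isnan(p):  # zero within-group variance with equal means
        return 1.0
    return float(p)


class DifferentialExpression:
    """Differential-expression model for one case/control comparison.

    Parameters
    ----------
    matrix
        Quantitation matrix (normalized or raw; see ``normalize``).
    meta
        ProteinMeta DataFrame indexed by accession with
        ``gene_symbol``, ``unique_peptides`` and ``id_fdr`` columns.
    case_group, control_group
        Group labels present in ``matrix.group_of``.
    params
        Filter thresholds; defaults to :class:`DEPParams`.
    normalize
        ``"median-scale"`` (default) or ``"none"``.

    Call :meth:`fit` to obtain :class:`DifferentialExpressionResults`.
    """

    def __init__(
        self,
        matrix: QuantMatrix,
        meta: pd.DataFrame,
        case_group: str,
        control_group: str,
        params: DEPParams | None = None,
        normalize: str = "median-scale",
    ) -> None:
        groups = set(matrix.group_of.values())
        for g in (case_group, control_group):
            if g not in groups:
                raise ValueError(f"group {g!r} not present in matrix (has {sorted(groups)})")
        if case_group == control_group:
            raise ValueError("case and control groups must differ")
        self.matrix = matrix
        self.meta = meta
        self.case_group = case_group
        self.control_group = control_group
        self.params = params or DEPParams()
        self.normalize = normalize

    def fit(self) -> "DifferentialExpressionResults":
        p = self.params
        norm = normalize_intensities(self.matrix, self.normalize)
        case_cols = norm.samples_in(self.case_group)
        ctrl_cols = norm.samples_in(self.control_group)

        vals = norm.intensities
        case = vals[case_cols].to_numpy(dtype=float)
        ctrl = vals[ctrl_cols].to_numpy(dtype=float)
        n_case = (~np.isnan(case)).sum(axis=1)
        n_ctrl = (~np.isnan(ctrl)).sum(axis=1)
        testable = (n_case >= 2) & (n_ctrl >= 2)

        meta = self.meta.reindex(vals.index)
        peptides = meta["unique_peptides"].to_numpy(dtype=float)
        id_fdr = meta["id_fdr"].to_numpy(dtype=float)
        genes = meta["gene_symbol"].astype(str).to_numpy()

        n = len(vals)
        fc_signed = np.full(n, np.nan)
        fc_mag = np.full(n, np.nan)
        pvals = np.full(n, np.nan)
        data_case = np.log2(case) if p.log_scale else case
        data_ctrl = np.log2(ctrl) if p.log_scale else ctrl
        for i in np.flatnonzero(testable):
            fc_signed[i], fc_mag[i] = fold_change(case[i], ctrl[i])
            pvals[i] = anova_p([data_case[i], data_ctrl[i]])

        p_for_gate = pvals.copy()
        if p.bh_correct:
            idx = np.flatnonzero(testable)
            if idx.size:
                p_for_gate[idx] = stats.false_discovery_control(pvals[idx], method="bh")

        pass_pep = peptides >= p.min_unique_peptides
        pass_fdr = id_fdr < p.max_id_fdr
        pass_fc = np.where(testable, fc_mag >= p.min_fc, False)
        pass_p = np.where(testable, p_for_gate <= p.max_p, False)
        is_dep = pass_pep & pass_fdr & pass_fc & pass_p & testable

        records = []
        for i, acc in enumerate(vals.index):
            records.append(
                DEPRecord(
                    accession=str(acc),
                    gene_symbol=genes[i],
                    fc_signed=float(fc_signed[i]),
                    fc_magnitude=float(fc_mag[i]),
                    p_value=float(p_for_gate[i]),
                    pass_peptides=bool(pass_pep[i]),
                    pass_fdr=bool(pass_fdr[i]),
                    pass_fc=bool(pass_fc[i]),
                    pass_p=bool(pass_p[i]),
                    is_dep=bool(is_dep[i]),
                    testable=bool(testable[i]),
                    reason="" if testable[i] else "fewer than 2 observed replicates in a group",
                )
            )
        return DifferentialExpressionResults(
            records=records,
            params=p,
            case_group=self.case_group,
            control_group=self.control_group,
        )


@dataclass
class DifferentialExpressionResults:
    """Fitted DEP-calling results: per-protein records and summaries."""

    records: list[DEPRecord]
    params: DEPParams
    case_group: str
    control_group: str
    _table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def table(self) -> pd.DataFrame:
        if self._table is None:
            self._table = pd.DataFrame([vars(r) for r in self.records])
        return self._table

    @property
    def deps(self) -> list[DEPRecord]:
        return [r for r in self.records if r.is_dep]

    @property
    def untestable(self) -> list[DEPRecord]:
        return [r for r in self.records if not r.testable]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        n = len(self.records)
        testable = sum(r.testable for r in self.records)
        lines = [
            "Differential expression ({} vs {})".format(self.case_group, self.control_group),
            "=" * 46,
            f"proteins              {n}",
            f"testable              {testable}",
            f"untestable (excluded) {n - testable}",
            f"fold-change gate      ≥ {self.params.min_fc}",
            f"p-value gate          ≤ {self.params.max_p}"
            + (" (BH-adjusted)" if self.params.bh_correct else ""),
            f"DEPs called           {len(self.deps)}",
        ]
        return "\n".join(lines)


def call_deps(
    matrix: QuantMatrix,
    meta: pd.DataFrame,
    params: DEPParams,
    case_group: str,
    control_group: str,
    normalize: str = "median-scale",
) -> list[DEPRecord]:
    """Functional wrapper: fit :class:`DifferentialExpression`, return records."""
    model = DifferentialExpression(
        matrix, meta, case_group, control_group, params=params, normalize=normalize
    )
    return model.fit().records


def evaluate_calls(
    records: Sequence[DEPRecord],
    dep_truth: dict[str, bool],
    condition_on_identified: bool = True,
) -> dict[str, float]:
    """Sensitivity and false-discovery proportion against planted truth.

    With ``condition_on_identified`` (default), performance is measured
    among proteins passing the static identification gates (unique
    peptides, id-FDR) and testable for differential expression — the
    usual notion of detection power, since those gates are independent
    of any planted group effect.
    """
    considered = [
        r
        for r in records
        if not condition_on_identified
        or (r.testable and r.pass_peptides and r.pass_fdr)
    ]
    tp = sum(1 for r in considered if r.is_dep and dep_truth[r.accession])
    fp = sum(1 for r in considered if r.is_dep and not dep_truth[r.accession])
    pos = sum(1 for r in considered if dep_truth[r.accession])
    called = tp + fp
    return {
        "n_considered": float(len(considered)),
        "n_called": float(called),
        "sensitivity": tp / pos if pos else float("nan"),
        "fdp": fp / called if called else 0.0,
    }
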