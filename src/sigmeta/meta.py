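"""Per-gene cross-dataset expression meta-analysis ("mega-analysis").

Each case-control expression study contributes, per gene, a log2
fold-change (LFC = mean case − mean control on the log2 scale) with its
unpooled (Welch-style) sampling variance

    var = s²_case / n_case + s²_control / n_control.

Per gene, effects from all studies containing it are pooled by inverse
variance.  Heterogeneity is measured by Cochran's Q against df = k − 1
with I² = 100·(Q − df)/Q truncated to zero.  Model selection follows the
rule: when Q ≤ df the between-study variance is indistinguishable from
sampling noise, I² is set to zero and the fixed-effect model is used;
otherwise the DerSimonian–Laird random-effects model with weights
1/(varᵢ + τ²) is used.  Inference is a two-sided Wald z-test on
pooled_lfc / se.  Significance calls use the raw thresholds
|LFC| > 1 and p < 0.05 (strict); BH q-values are reported alongside but
do not gate the call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_fdr

log = logging.getLogger(__name__)

#: matrices whose maximum exceeds this are assumed linear-scale
LINEAR_SCALE_MAX = 30.0


@dataclass
class ExpressionDataset:
    """One study's genes × samples expression matrix with group labels.

    ``matrix`` rows are genes (unique symbols after probe collapsing),
    columns are samples; ``groups`` maps each sample to ``"case"`` or
    ``"control"``.
    """

    dataset_id: str
    matrix: pd.DataFrame
    groups: pd.Series
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.matrix.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(
                f"{self.dataset_id}: samples without group label: {missing[:5]}"
            )
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"{self.dataset_id}: unknown group labels {sorted(bad)}")
        if self.matrix.index.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate gene identifiers")

    @property
    def n_case(self) -> int:
        return int((self.groups == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.groups == "control").sum())

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def case_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[:, self.groups == "case"]

    def control_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[:, self.groups == "control"]


@dataclass(frozen=True)
class DatasetEffect:
    """Per-gene, per-dataset effect size: LFC and its sampling variance."""

    dataset_id: str
    gene: str
    lfc: float
    var: float
    n_case: int
    n_control: int


@dataclass(frozen=True)
class MetaResult:
    """Pooled per-gene result of the cross-dataset analysis."""

    gene: str
    k: int
    pooled_lfc: float
    se: float
    p: float
    Q: float
    df: int
    isq: float
    tau2: float
    model: str  # "fixed" | "random"


@dataclass
class QQReport:
    """Per-gene standardized statistics of one dataset vs N(0, 1)."""

    dataset_id: str
    statistics: np.ndarray          # sorted standardized per-gene z = lfc/sqrt(var)
    theoretical_quantiles: np.ndarray
    deviation: float                # Kolmogorov–Smirnov distance to N(0,1)
    systematic_bias: bool


def normalize_log2(
    dataset: ExpressionDataset, linear_max: float = LINEAR_SCALE_MAX
) -> ExpressionDataset:
    """Put the matrix on a log2 scale if it looks linear.

    Heuristic: a maximum value above ``linear_max`` marks a linear-scale
    matrix, which is transformed as log2(x + 1); otherwise the matrix is
    returned unchanged.  ``log_transformed`` records which branch ran.
    """
    values = dataset.matrix.to_numpy()
    if not np.isfinite(values).all():
        raise ValueError(f"{dataset.dataset_id}: non-finite expression values")
    if values.size and values.max() > linear_max:
        if (values < 0).any():
            raise ValueError(
                f"{dataset.dataset_id}: negative values on the linear branch; "
                "cannot log-transform"
            )
        log.info("%s: detected linear scale, applying log2(x+1)", dataset.dataset_id)
        return replace(
            dataset,
            matrix=pd.DataFrame(
                np.log2(values + 1.0),
                index=dataset.matrix.index,
                columns=dataset.matrix.columns,
            ),
            log_transformed=True,
        )
    return replace(dataset, log_transformed=False)


def collapse_probes(
    matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probes × samples matrix to genes × samples by per-sample median.

    Probes missing from the mapping are dropped.  Gene symbols are
    upper-cased.  Deterministic: output rows sorted by gene symbol.
    """
    if not probe_to_gene:
        log.warning("empty probe-to-gene mapping: returning empty matrix")
        return matrix.iloc[0:0]
    genes = pd.Series(
        {p: str(g).upper() for p, g in probe_to_gene.items()}, name="gene"
    )
    kept = matrix.loc[matrix.index.intersection(genes.index)]
    collapsed = kept.groupby(genes.reindex(kept.index)).median()
    collapsed.index.name = matrix.index.name
    return collapsed.sort_index()


def dataset_effects(
    dataset: ExpressionDataset, genes: Iterable[str] | None = None
) -> pd.DataFrame:
    """Vectorized per-gene LFC and Welch variance for one dataset.

    Returns a DataFrame indexed by gene with columns ``lfc``, ``var``,
    ``n_case``, ``n_control``.  Requires at least two samples per group.
    """
    if dataset.n_case < 2 or dataset.n_control < 2:
        raise ValueError(
            f"{dataset.dataset_id}: need >= 2 samples per group for a variance "
            f"(n_case={dataset.n_case}, n_control={dataset.n_control})"
        )
    mat = dataset.matrix
    if genes is not None:
        mat = mat.loc[mat.index.intersection(list(genes))]
    case = mat.loc[:, dataset.groups == "case"].to_numpy(float)
    ctrl = mat.loc[:, dataset.groups == "control"].to_numpy(float)
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    var = case.var(axis=1, ddof=1) / case.shape[1] + ctrl.var(axis=1, ddof=1) / ctrl.shape[1]
    return pd.DataFrame(
        {
            "lfc": lfc,
            "var": var,
            "n_case": dataset.n_case,
            "n_control": dataset.n_control,
        },
        index=mat.index,
    )


def dataset_effect(dataset: ExpressionDataset, gene: str) -> DatasetEffect | None:
    """Effect of ``gene`` in one dataset, or None when the gene is absent."""
    gene = gene.upper()
    if gene not in dataset.matrix.index:
        return None
    row = dataset_effects(dataset, [gene]).loc[gene]
    return DatasetEffect(
        dataset_id=dataset.dataset_id,
        gene=gene,
        lfc=float(row["lfc"]),
        var=float(row["var"]),
        n_case=dataset.n_case,
        n_control=dataset.n_control,
    )


def _theta_var(effects: Sequence[DatasetEffect]) -> tuple[np.ndarray, np.ndarray]:
    if not effects:
        raise ValueError("no effects supplied")
    theta = np.array([e.lfc for e in effects], float)
    var = np.array([e.var for e in effects], float)
    for e in effects:
        if e.var <= 0:
            raise ValueError(f"non-positive variance in dataset {e.dataset_id}")
    return theta, var


def cochran_q(effects: Sequence[DatasetEffect]) -> tuple[float, int]:
    """Cochran's heterogeneity statistic Q and its degrees of freedom k − 1."""
    theta, var = _theta_var(effects)
    w = 1.0 / var
    pooled = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - pooled) ** 2))
    return q, len(effects) - 1


def i_squared(Q: float, df: int) -> float:
    """Heterogeneity percentage: 0 when Q ≤ df, else 100·(Q − df)/Q."""
    if Q < 0 or df < 0:
        raise ValueError("Q and df must be non-negative")
    if Q <= df:
        return 0.0
    return 100.0 * (Q - df) / Q


def dl_tau2(effects: Sequence[DatasetEffect]) -> float:
    """DerSimonian–Laird moment estimator of between-study variance τ².

    τ² = max(0, (Q − df) / (Σw − Σw²/Σw)) with fixed-effect weights
    w = 1/var.  Requires at least two studies.
    """
    if len(effects) < 2:
        raise ValueError(f"need >= 2 effects for tau^2, got {len(effects)}")
    _, var = _theta_var(effects)
    q, df = cochran_q(effects)
    w = 1.0 / var
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c <= 0:
        return 0.0
    return max(0.0, (q - df) / c)


def pool(effects: Sequence[DatasetEffect]) -> MetaResult:
    """Inverse-variance pooling with heterogeneity-driven model selection.

    Fixed-effect weights when Q ≤ df (and I² = 0 by the truncation rule);
    DerSimonian–Laird random-effects weights 1/(var + τ²) otherwise.
    p is the two-sided normal tail of pooled_lfc / se.
    """
    if len(effects) < 2:
        raise ValueError(f"need >= 2 effects to pool, got {len(effects)}")
    theta, var = _theta_var(effects)
    q, df = cochran_q(effects)
    isq = i_squared(q, df)
    tau2 = dl_tau2(effects)
    if q <= df:
        model, w = "fixed", 1.0 / var
    else:
        model, w = "random", 1.0 / (var + tau2)
    pooled = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = max(p, np.nextafter(0.0, 1.0))  # keep p in (0, 1]
    return MetaResult(
        gene=effects[0].gene,
        k=len(effects),
        pooled_lfc=pooled,
        se=se,
        p=p,
        Q=q,
        df=df,
        isq=isq,
        tau2=tau2,
        model=model,
    )


def mega_analysis(
    datasets: Sequence[ExpressionDataset], genes: Iterable[str] | None = None
) -> tuple[list[MetaResult], list[str]]:
    """Pool every gene across all datasets that contain it.

    Genes found in fewer than two datasets cannot be pooled and are
    returned in the second element ("unanalyzable").  Results are sorted
    by p ascending (ties broken by gene symbol for determinism).
    """
    if len(datasets) < 2:
        raise ValueError(f"need >= 2 datasets, got {len(datasets)}")
    if genes is None:
        universe: set[str] = set()
        for ds in datasets:
            universe |= set(ds.genes)
    else:
        universe = {g.upper() for g in genes}
    if not universe:
        return [], []

    per_ds = [(ds, dataset_effects(ds)) for ds in datasets]
    results: list[MetaResult] = []
    unanalyzable: list[str] = []
    for gene in sorted(universe):
        effects = [
            DatasetEffect(
                dataset_id=ds.dataset_id,
                gene=gene,
                lfc=float(tab.at[gene, "lfc"]),
                var=float(tab.at[gene, "var"]),
                n_case=ds.n_case,
                n_control=ds.n_control,
            )
            for ds, tab in per_ds
            if gene in tab.index
        ]
        if len(effects) < 2:
            unanalyzable.append(gene)
            continue
        results.append(pool(effects))
    results.sort(key=lambda r: (r.p, r.gene))
    return results, unanalyzable


def results_table(results: Sequence[MetaResult]) -> pd.DataFrame:
    """Full results table with BH q-values appended (reported, not used for calls)."""
    df = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "k": r.k,
                "pooled_lfc": r.pooled_lfc,
                "se": r.se,
                "p": r.p,
                "Q": r.Q,
                "df": r.df,
                "isq": r.isq,
                "tau2": r.tau2,
                "model": r.model,
            }
            for r in results
        ]
    )
    if not df.empty:
        df.insert(5, "q_bh", bh_fdr(df["p"].tolist()))
    return df


def significant_genes(
    results: Sequence[MetaResult], lfc_cut: float = 1.0, p_cut: float = 0.05
) -> list[MetaResult]:
    """Apply the significance rule: |pooled LFC| > lfc_cut AND p < p_cut (strict)."""
    return [
        r
        for r in results
        if (r.pooled_lfc > lfc_cut or r.pooled_lfc < -lfc_cut) and r.p < p_cut
    ]


def volcano_table(results: Sequence[MetaResult]) -> pd.DataFrame:
    """Gene, pooled LFC and −log10 p, for volcano plotting."""
    return pd.DataFrame(
        [
            {"gene": r.gene, "pooled_lfc": r.pooled_lfc, "neg_log10_p": -math.log10(r.p)}
            for r in results
        ]
    )


def forest_data(
    gene: str, effects: Sequence[DatasetEffect], pooled: MetaResult
) -> pd.DataFrame:
    """Forest-plot table: one row per study plus a pooled summary row.

    Per-study 95% CI is lfc ± 1.96·√var; weights are the pooling weights
    of the selected model, normalized to percent (they sum to 100).
    """
    theta, var = _theta_var(effects)
    tau2 = pooled.tau2 if pooled.model == "random" else 0.0
    w = 1.0 / (var + tau2)
    w_pct = 100.0 * w / w.sum()
    rows = [
        {
            "dataset_id": e.dataset_id,
            "lfc": e.lfc,
            "ci_low": e.lfc - 1.96 * math.sqrt(e.var),
            "ci_high": e.lfc + 1.96 * math.sqrt(e.var),
            "weight_pct": float(wp),
            "row": "study",
        }
        for e, wp in zip(effects, w_pct)
    ]
    rows.append(
        {
            "dataset_id": f"pooled ({pooled.model})",
            "lfc": pooled.pooled_lfc,
            "ci_low": pooled.pooled_lfc - 1.96 * pooled.se,
            "ci_high": pooled.pooled_lfc + 1.96 * pooled.se,
            "weight_pct": 100.0,
            "row": "summary",
        }
    )
    df = pd.DataFrame(rows)
    df.insert(0, "gene", gene.upper())
    return df


def qq_check(
    dataset: ExpressionDataset, bias_threshold: float = 0.1
) -> QQReport:
    """Check one dataset's per-gene statistics against a standard normal.

    Per gene, z = lfc/√var; the vector is standardized robustly (median
    location, MAD scale calibrated to the normal), sorted, and compared
    to N(0, 1) quantiles.  Robust standardization keeps a handful of
    genuinely extreme genes from inflating the scale, so the check flags
    only distribution-wide distortion.  The deviation is the
    Kolmogorov–Smirnov distance; ``systematic_bias`` flags deviation
    above ``bias_threshold``.  A dataset whose genes carry no spread at
    all is degenerate and rejected.
    """
    tab = dataset_effects(dataset)
    z = (tab["lfc"] / np.sqrt(tab["var"])).to_numpy(float)
    z = z[np.isfinite(z)]
    scale = float(stats.median_abs_deviation(z, scale="normal")) if z.size else 0.0
    if z.size < 2 or scale == 0.0:
        raise ValueError(
            f"{dataset.dataset_id}: degenerate input, no spread in per-gene statistics"
        )
    standardized = np.sort((z - np.median(z)) / scale)
    n = standardized.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    deviation = float(stats.kstest(standardized, "norm").statistic)
    return QQReport(
        dataset_id=dataset.dataset_id,
        statistics=standardized,
        theoretical_quantiles=theo,
        deviation=deviation,
        systematic_bias=deviation > bias_threshold,
    )
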