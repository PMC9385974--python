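"""Empirical-Bayes moderated-t differential expression and membership tables.

The statistical engine is the standard hierarchical model for gene-wise
variances: the prior is a scaled inverse chi-square with hyperparameters
``(d0, s0_sq)`` estimated by moment matching on log residual variances; the
posterior variance shrinks each gene's sample variance toward the prior, and
the moderated t gains ``d0`` degrees of freedom.

No multiple-testing adjustment is applied to DEG calls: calls use a raw
p-value cutoff combined with a fold-change cutoff. This mirrors a common
two-dataset screening design and is a deliberate (documented) statistical
caveat — intersecting two datasets stands in for formal FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import (
    ConfigError,
    DataError,
    DegenerateDataError,
    DesignError,
)
from .gene_sets import GeneSet, normalize_symbol

PLATFORMS = ("count", "intensity")
GROUPS = ("case", "control")

#: Map from gene-set category to membership (DE) label.
CATEGORY_LABELS = {
    "apoptosis": "DEARG",
    "necroptosis": "DENRG",
    "pyroptosis": "DEPRG",
}
MEMBERSHIP_LABELS = ("DEARG", "DENRG", "DEPRG")


@dataclass
class ExpressionDataset:
    """A genes x samples matrix with two-group labels.

    ``values`` has one row per entry of ``gene_ids`` and one column per
    entry of ``group_labels`` (each ``"case"`` or ``"control"``).
    """

    values: np.ndarray
    gene_ids: list
    group_labels: list
    platform: str
    label: str = "dataset"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        if self.values.shape[0] != len(self.gene_ids):
            raise DataError("row count does not match number of gene ids")
        if self.values.shape[1] != len(self.group_labels):
            raise DataError("column count does not match number of group labels")
        if self.platform not in PLATFORMS:
            raise DataError(f"platform must be one of {PLATFORMS}")
        bad = set(self.group_labels) - set(GROUPS)
        if bad:
            raise DataError(f"unknown group labels: {sorted(bad)}")
        for g in GROUPS:
            if self.group_labels.count(g) < 2:
                raise DesignError(f"group {g!r} has fewer than 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite values")

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.group_labels) if g == group])

    @classmethod
    def from_tsv(cls, expression_path, groups_path, platform: str,
                 label: str | None = None) -> "ExpressionDataset":
        """Load from an expression TSV (first column = gene, header = sample
        ids) and a two-column sample->group assignment TSV."""
        expr = pd.read_csv(expression_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
        missing = [s for s in expr.columns if s not in groups.index]
        if missing:
            raise DataError(f"samples without group assignment: {missing}")
        return cls(
            values=expr.to_numpy(dtype=float),
            gene_ids=list(expr.index),
            group_labels=[str(groups[s]) for s in expr.columns],
            platform=platform,
            label=label or str(expression_path),
        )

    def to_tsv(self, expression_path, groups_path) -> None:
        sample_ids = [f"S{i + 1}_{g}" for i, g in enumerate(self.group_labels)]
        pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene"),
                     columns=sample_ids).to_csv(expression_path, sep="\t")
        pd.DataFrame({"group": self.group_labels},
                     index=pd.Index(sample_ids, name="sample")
                     ).to_csv(groups_path, sep="\t")


@dataclass
class ModeratedTestParams:
    """Empirical-Bayes hyperparameters of the variance prior.

    ``d0`` is allowed to be 0 (no moderation: the ordinary pooled t) or
    ``inf`` (complete shrinkage: a z-test against ``s0_sq``).
    """

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 >= 0):
            raise ConfigError("d0 must be >= 0 (or inf)")
        if not (self.s0_sq > 0):
            raise ConfigError("s0_sq must be > 0")


def prepare_matrix(dataset: ExpressionDataset, transform: str | None = None
                   ) -> ExpressionDataset:
    """Put a dataset on the log2 scale expected by the linear-model fit.

    Count platform defaults to ``log2p1`` (log2(x+1)); options are ``none``,
    ``log2p1`` and ``log2cpm`` (log2 counts-per-million with pseudocount
    0.5). Intensity platform is passed through unchanged (assumed already on
    a log scale).
    """
    if dataset.platform == "intensity":
        return dataset
    if transform is None:
        transform = "log2p1"
    if np.any(dataset.values < 0):
        raise DataError("negative values on count platform")
    if transform == "none":
        values = dataset.values
    elif transform == "log2p1":
        values = np.log2(dataset.values + 1.0)
    elif transform == "log2cpm":
        lib = dataset.values.sum(axis=0)
        values = np.log2((dataset.values + 0.5) / (lib + 1.0) * 1e6)
    else:
        raise ConfigError(f"unknown transform {transform!r}")
    return ExpressionDataset(values=values, gene_ids=dataset.gene_ids,
                             group_labels=dataset.group_labels,
                             platform=dataset.platform, label=dataset.label)


def fit_two_group(dataset: ExpressionDataset):
    """Per-gene two-group fit on the prepared (log-scale) matrix.

    Returns
    -------
    (log2fc, s_g_sq, d_g)
        ``log2fc``: mean(case) - mean(control) per gene;
        ``s_g_sq``: pooled within-group variance per gene;
        ``d_g``: residual degrees of freedom (scalar, n1 + n2 - 2).
    """
    case = dataset.values[:, dataset.group_columns("case")]
    control = dataset.values[:, dataset.group_columns("control")]
    n1, n2 = case.shape[1], control.shape[1]
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (control - control.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    d_g = n1 + n2 - 2
    return log2fc, ss / d_g, d_g


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    # trigamma(x) ~ 1/x + 1/(2x^2); start from the 1/x approximation
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * abs(x):
            break
    return float(x)


def estimate_prior(s_sq: Sequence[float], d_g: int, eps: float = 1e-9
                   ) -> ModeratedTestParams:
    """Estimate (d0, s0_sq) by moment matching on log variances.

    With ``z_g = log(s_g^2)`` and ``e_g = z_g - digamma(d_g/2) + log(d_g/2)``,
    the excess spread of the ``e_g`` beyond trigamma(d_g/2) identifies
    trigamma(d0/2); the mean identifies ``s0_sq``. When the excess spread is
    <= ``eps`` the prior degrees of freedom are infinite and
    ``s0_sq = exp(mean(e_g))``.

    Zero variances are floored to the smallest positive variance observed.
    Requires at least 10 genes.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq)]
    if len(s_sq) < 10:
        raise DegenerateDataError("need >= 10 finite variances to estimate the prior")
    positive = s_sq[s_sq > 0]
    if len(positive) == 0:
        raise DegenerateDataError("all residual variances are zero")
    s_sq = np.where(s_sq <= 0, positive.min(), s_sq)

    z = np.log(s_sq)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_bar = e.mean()
    G = len(e)
    excess = ((e - e_bar) ** 2).sum() / (G - 1) - special.polygamma(1, d_g / 2.0)
    if excess <= eps:
        return ModeratedTestParams(d0=np.inf, s0_sq=float(np.exp(e_bar)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModeratedTestParams(d0=d0, s0_sq=s0_sq)


def moderated_t(log2fc, s_g_sq, d_g, params: ModeratedTestParams,
                n_case: int, n_control: int):
    """Moderated t statistics and two-sided p-values.

    Posterior variance: ``(d0*s0_sq + d_g*s_g_sq) / (d0 + d_g)``;
    t = log2fc / sqrt(posterior * (1/n1 + 1/n2)); p from a t distribution
    with ``d0 + d_g`` df (standard normal when d0 is infinite).
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s_g_sq = np.asarray(s_g_sq, dtype=float)
    if np.isinf(params.d0):
        s_tilde = np.full_like(log2fc, params.s0_sq)
    elif params.d0 == 0:
        s_tilde = s_g_sq
    else:
        s_tilde = (params.d0 * params.s0_sq + d_g * s_g_sq) / (params.d0 + d_g)
    if np.any(s_tilde <= 0):
        raise DegenerateDataError("zero posterior variance; statistic undefined")
    se = np.sqrt(s_tilde * (1.0 / n_case + 1.0 / n_control))
    t = log2fc / se
    if np.isinf(params.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=params.d0 + d_g)
    return t, p


def run_de(dataset: ExpressionDataset, transform: str | None = None
           ) -> pd.DataFrame:
    """Full per-dataset differential-expression analysis.

    Returns a DataFrame indexed by gene with columns
    ``log2fc, s_g_sq, t, p_value`` (plus the fitted prior as attrs).
    """
    prepared = prepare_matrix(dataset, transform=transform)
    log2fc, s_sq, d_g = fit_two_group(prepared)
    params = estimate_prior(s_sq, d_g)
    n1 = len(prepared.group_columns("case"))
    n2 = len(prepared.group_columns("control"))
    t, p = moderated_t(log2fc, s_sq, d_g, params, n1, n2)
    out = pd.DataFrame(
        {"log2fc": log2fc, "s_g_sq": s_sq, "t": t, "p_value": p},
        index=pd.Index(prepared.gene_ids, name="gene"),
    )
    out.attrs["d0"] = params.d0
    out.attrs["s0_sq"] = params.s0_sq
    out.attrs["d_g"] = d_g
    return out


def call_degs(result: pd.DataFrame, p_cut: float = 0.05, lfc_cut: float = 1.0
              ) -> Dict[str, str]:
    """Call DEGs at strict cutoffs: p < p_cut and |log2fc| > lfc_cut.

    Returns gene -> direction ("up"/"down") preserving the result's order.
    """
    called = {}
    for gene, row in zip(result.index, result.itertuples(index=False)):
        if row.p_value < p_cut and abs(row.log2fc) > lfc_cut:
            called[str(gene)] = "up" if row.log2fc > 0 else "down"
    return called


def intersect_datasets(degs_by_dataset: Mapping[str, Mapping[str, str]]
                       ) -> Dict[str, Dict[str, str]]:
    """Genes called in every dataset, with per-dataset directions retained.

    Intersection is on normalized symbols and ignores direction concordance
    (genes frequently flip sign between platforms). Order follows the first
    dataset's DEG order.
    """
    if len(degs_by_dataset) < 2:
        raise DesignError("need >= 2 datasets to intersect")
    normed = {
        label: {normalize_symbol(g): d for g, d in degs.items()}
        for label, degs in degs_by_dataset.items()
    }
    labels = list(normed)
    common: Dict[str, Dict[str, str]] = {}
    for gene in normed[labels[0]]:
        if all(gene in normed[lab] for lab in labels[1:]):
            common[gene] = {lab: normed[lab][gene] for lab in labels}
    return common


@dataclass
class MembershipRow:
    gene: str
    directions: dict  # dataset label -> "up"/"down"
    categories: frozenset  # subset of MEMBERSHIP_LABELS


@dataclass
class MembershipTable:
    """Per-gene DE direction per dataset plus PCD-category memberships."""

    rows: list
    dataset_labels: tuple = ()

    def __post_init__(self):
        genes = [r.gene for r in self.rows]
        if len(set(genes)) != len(genes):
            raise DataError("duplicate genes in membership table")
        for r in self.rows:
            if not r.categories:
                raise DataError(f"membership row {r.gene} has no category")

    def __len__(self):
        return len(self.rows)

    def genes(self) -> list:
        return [r.gene for r in self.rows]

    def category_counts(self) -> Dict[str, int]:
        counts = {lab: 0 for lab in MEMBERSHIP_LABELS}
        for r in self.rows:
            for c in r.categories:
                counts[c] = counts.get(c, 0) + 1
        return counts

    def genes_in_category(self, label: str) -> list:
        return [r.gene for r in self.rows if label in r.categories]

    def to_frame(self) -> pd.DataFrame:
        labels = self.dataset_labels or sorted(
            {lab for r in self.rows for lab in r.directions}
        )
        records = []
        for r in self.rows:
            rec = {"gene": r.gene}
            for lab in labels:
                rec[lab] = r.directions.get(lab, "")
            rec["categories"] = ",".join(sorted(r.categories))
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MembershipTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        labels = tuple(c for c in df.columns if c not in ("gene", "categories"))
        rows = [
            MembershipRow(
                gene=rec["gene"],
                directions={lab: rec[lab] for lab in labels if pd.notna(rec[lab])},
                categories=frozenset(str(rec["categories"]).split(",")),
            )
            for rec in df.to_dict("records")
        ]
        return cls(rows=rows, dataset_labels=labels)


def build_membership(common_degs: Mapping[str, Mapping[str, str]],
                     pcd_sets: Sequence[GeneSet]) -> MembershipTable:
    """Cross common DEGs with PCD gene sets to build the membership table.

    A row is emitted for each common DEG found in at least one PCD set; the
    row's categories are the membership labels of all sets containing it.
    """
    categories = [s.category for s in pcd_sets]
    if len(set(categories)) != len(categories):
        raise ConfigError("PCD gene sets must have distinct categories")
    for s in pcd_sets:
        if s.category not in CATEGORY_LABELS:
            raise ConfigError(
                f"gene set {s.name!r} has category {s.category!r}; "
                f"expected one of {sorted(CATEGORY_LABELS)}"
            )
    labels = tuple(
        dict.fromkeys(lab for degs in common_degs.values() for lab in degs)
    )
    rows = []
    for gene, directions in common_degs.items():
        cats = frozenset(
            CATEGORY_LABELS[s.category] for s in pcd_sets if gene in s
        )
        if cats:
            rows.append(MembershipRow(gene=gene, directions=dict(directions),
                                      categories=cats))
    return MembershipTable(rows=rows, dataset_labels=labels)


def venn_counts(table: MembershipTable) -> Dict[frozenset, int]:
    """Counts of genes per non-empty category combination (7 combos).

    The combination keys partition the table: values sum to ``len(table)``.
    """
    from itertools import combinations

    combos = [
        frozenset(c)
        for r in (1, 2, 3)
        for c in combinations(MEMBERSHIP_LABELS, r)
    ]
    counts = {c: 0 for c in combos}
    for row in table.rows:
        counts[frozenset(row.categories)] += 1
    return counts
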