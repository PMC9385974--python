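"""Synthetic inputs with known ground truth, plus in-study worked fixtures.

Everything the pipeline consumes can be generated here: two-group expression
matrices with planted log2 fold changes and heterogeneous gene-wise
variances, cell-death gene lists, and noisy multi-source interaction tables
derived from a ground-truth sponge structure. Each artifact draws from its
own RNG stream spawned from the master seed, so e.g. adding a prediction
source never perturbs the expression draw.

The module also packages two worked fixtures transcribed from the study this
pipeline mirrors: the 15-row DEG membership table and the eight listed
regulatory axes (which deduplicate to seven unique triples).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .cerna import InteractionEvidence
from .diffexpr import ExpressionDataset, MembershipRow, MembershipTable
from .errors import ConfigError
from .gene_sets import GeneSet
from .hubs import RegulatoryAxis

# RNG stream ids (fixed offsets under the master seed)
_STREAM_EXPRESSION = 0
_STREAM_TRUTH = 1
_STREAM_SOURCE_BASE = 100


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass
class SimulationConfig:
    """Parameters of a two-group expression simulation."""

    n_genes: int = 1000
    n_per_group: int = 3
    platform: str = "intensity"
    de_fraction: float = 0.1
    effect_size_log2: float = 2.0
    variance_shape: float = 4.0  # prior df of the inverse-chi-square variances
    baseline_variance: float = 0.05  # prior scale (s0^2)
    nb_dispersion: float = 0.1
    libsize_log_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2 (variance not estimable)")
        if self.platform not in ("count", "intensity"):
            raise ConfigError("platform must be 'count' or 'intensity'")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ConfigError("de_fraction must be in [0, 1]")
        if self.effect_size_log2 < 0:
            raise ConfigError("effect_size_log2 must be >= 0")
        if self.variance_shape <= 0:
            raise ConfigError("variance_shape must be > 0")


@dataclass
class GroundTruth:
    """Planted effects and sponge structure behind a simulation."""

    de_genes: Dict[str, float] = field(default_factory=dict)  # gene -> signed lfc
    true_interactions: frozenset = frozenset()  # (regulator, class, target)
    true_axes: frozenset = frozenset()  # (lncRNA, miRNA, mRNA)

    def __post_init__(self):
        interactions = set(self.true_interactions)
        for l, m, g in self.true_axes:
            if (l, "lncRNA", m) not in interactions or (m, "miRNA", g) not in interactions:
                raise ConfigError(
                    f"axis ({l}, {m}, {g}) not backed by two true interactions")

    def to_json(self, path) -> None:
        payload = {
            "de_genes": self.de_genes,
            "true_interactions": sorted(list(t) for t in self.true_interactions),
            "true_axes": sorted(list(t) for t in self.true_axes),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            de_genes=dict(payload["de_genes"]),
            true_interactions=frozenset(tuple(t) for t in payload["true_interactions"]),
            true_axes=frozenset(tuple(t) for t in payload["true_axes"]),
        )


@dataclass
class SourceNoiseModel:
    """Per-source reporting noise for interaction predictions."""

    sensitivity: float = 0.9
    fpr_rate: float = 0.5  # spurious pairs per source, as a fraction of truths
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ConfigError("sensitivity must be in [0, 1]")
        if self.fpr_rate < 0:
            raise ConfigError("fpr_rate must be >= 0")


def simulate_expression(config: SimulationConfig,
                        gene_ids: Sequence[str] | None = None,
                        label: str = "simulated",
                        ) -> Tuple[ExpressionDataset, GroundTruth]:
    """Simulate a two-group dataset with planted log2 fold changes.

    Intensity platform: Gaussian log-scale values with gene variances drawn
    from ``s0^2 * d0 / chi2(d0)`` (matching the moderated-t hierarchical
    model). Count platform: negative-binomial counts whose log2 expectation
    shifts by the planted effect, with log-normal library-size factors.
    """
    rng = _rng(config.seed, _STREAM_EXPRESSION)
    G, n = config.n_genes, config.n_per_group
    if gene_ids is None:
        gene_ids = [f"G{i + 1:05d}" for i in range(G)]
    elif len(gene_ids) != G:
        raise ConfigError("gene_ids length must equal n_genes")

    n_de = int(round(config.de_fraction * G))
    de_idx = rng.choice(G, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    shift = np.zeros(G)
    shift[de_idx] = signs * config.effect_size_log2

    group_labels = ["case"] * n + ["control"] * n
    if config.platform == "intensity":
        variances = (config.baseline_variance * config.variance_shape
                     / rng.chisquare(config.variance_shape, size=G))
        base = rng.normal(7.0, 1.0, size=G)
        noise = rng.normal(size=(G, 2 * n)) * np.sqrt(variances)[:, None]
        values = base[:, None] + noise
        values[:, :n] += shift[:, None]
    else:
        base_log2 = rng.uniform(3.0, 9.0, size=G)
        lib = np.exp(rng.normal(0.0, config.libsize_log_sd, size=2 * n))
        mu = 2.0 ** (base_log2[:, None] + np.where(
            np.arange(2 * n)[None, :] < n, shift[:, None], 0.0))
        mu = mu * lib[None, :]
        r = 1.0 / config.nb_dispersion
        values = rng.negative_binomial(r, r / (r + mu)).astype(float)

    dataset = ExpressionDataset(values=values, gene_ids=list(gene_ids),
                                group_labels=group_labels,
                                platform=config.platform, label=label)
    truth = GroundTruth(de_genes={gene_ids[i]: float(shift[i]) for i in de_idx})
    return dataset, truth


def simulate_cerna_truth(mrnas: Sequence[str],
                         n_lncrnas: int = 8,
                         n_mirnas: int = 12,
                         mirnas_per_mrna: int = 3,
                         lncrnas_per_mirna: int = 2,
                         seed: int = 0) -> GroundTruth:
    """Plant a ground-truth sponge structure over a given mRNA set.

    Each mRNA is targeted by ``mirnas_per_mrna`` miRNAs; each used miRNA is
    sponged by ``lncrnas_per_mirna`` lncRNAs. Every lncRNA-miRNA-mRNA path
    through the planted interactions is a true axis.
    """
    if not mrnas:
        raise ConfigError("mrnas must be non-empty")
    if mirnas_per_mrna > n_mirnas or lncrnas_per_mirna > n_lncrnas:
        raise ConfigError("per-node fan-in exceeds pool size")
    rng = _rng(seed, _STREAM_TRUTH)
    mirna_pool = [f"miR-sim-{i + 1}" for i in range(n_mirnas)]
    lncrna_pool = [f"lncRNA-sim-{i + 1}" for i in range(n_lncrnas)]
    interactions = set()
    for gene in mrnas:
        for m in rng.choice(n_mirnas, size=mirnas_per_mrna, replace=False):
            interactions.add((mirna_pool[m], "miRNA", gene))
    used_mirnas = sorted({reg for reg, cls, _ in interactions if cls == "miRNA"})
    for m in used_mirnas:
        for l in rng.choice(n_lncrnas, size=lncrnas_per_mirna, replace=False):
            interactions.add((lncrna_pool[l], "lncRNA", m))
    sponge_of = {}
    for reg, cls, tgt in interactions:
        if cls == "lncRNA":
            sponge_of.setdefault(tgt, set()).add(reg)
    axes = {
        (l, m, g)
        for m, cls, g in interactions if cls == "miRNA"
        for l in sponge_of.get(m, ())
    }
    return GroundTruth(de_genes={}, true_interactions=frozenset(interactions),
                       true_axes=frozenset(axes))


def simulate_prediction_sources(truth: GroundTruth, n_sources: int,
                                noise: SourceNoiseModel,
                                regulator_classes: Sequence[str] = ("miRNA", "lncRNA"),
                                source_prefix: str = "source",
                                ) -> List[List[InteractionEvidence]]:
    """Generate per-source evidence tables from a ground-truth structure.

    Each source reports each true interaction independently with probability
    ``sensitivity`` and adds spurious pairs sampled (without replacement,
    never duplicating a true pair) from non-interacting same-class
    regulator/target combinations; the expected spurious count per class is
    ``fpr_rate`` times the true count.
    """
    if n_sources < 1:
        raise ConfigError("n_sources must be >= 1")
    truths_by_class = {
        cls: sorted((reg, tgt) for reg, c, tgt in truth.true_interactions
                    if c == cls)
        for cls in regulator_classes
    }
    if not any(truths_by_class.values()):
        raise ConfigError("truth has no interactions of the requested classes")
    target_class = {"miRNA": "mRNA", "lncRNA": "miRNA"}

    tables: List[List[InteractionEvidence]] = []
    for i in range(n_sources):
        rng = _rng(noise.seed, _STREAM_SOURCE_BASE + i)
        label = f"{source_prefix}_{i + 1}"
        rows: List[InteractionEvidence] = []
        for cls in regulator_classes:
            true_pairs = truths_by_class[cls]
            if not true_pairs:
                continue
            keep = rng.random(len(true_pairs)) < noise.sensitivity
            reported = [p for p, k in zip(true_pairs, keep) if k]
            true_set = set(true_pairs)
            regulators = sorted({r for r, _ in true_pairs})
            targets = sorted({t for _, t in true_pairs})
            candidates = [
                (r, t) for r in regulators for t in targets
                if (r, t) not in true_set
            ]
            n_spurious = min(int(round(noise.fpr_rate * len(true_pairs))),
                             len(candidates))
            if n_spurious:
                picks = rng.choice(len(candidates), size=n_spurious, replace=False)
                reported.extend(candidates[j] for j in picks)
            rows.extend(
                InteractionEvidence(source=label, regulator=r,
                                    regulator_class=cls, target=t,
                                    target_class=target_class[cls])
                for r, t in sorted(reported)
            )
        tables.append(rows)
    return tables


# ---------------------------------------------------------------------------
# worked fixtures (transcribed tables)

_DATASET_A = "GSE58720"
_DATASET_B = "GSE131193"

# gene, direction in dataset A, direction in dataset B, membership labels
_MEMBERSHIP_ROWS = [
    ("Bax", "up", "down", ("DEARG", "DENRG", "DEPRG")),
    ("Pycard", "up", "down", ("DEARG", "DENRG", "DEPRG")),
    ("Zbp1", "up", "down", ("DEARG", "DENRG", "DEPRG")),
    ("Tnfrsf10b", "up", "down", ("DEARG", "DENRG")),
    ("Il1b", "up", "down", ("DENRG", "DEPRG")),
    ("Tnf", "up", "down", ("DENRG", "DEPRG")),
    ("Cd14", "up", "down", ("DEARG", "DEPRG")),
    ("Mapt", "down", "up", ("DEARG",)),
    ("Cxcl1", "up", "down", ("DENRG",)),
    ("Ripk3", "up", "down", ("DENRG",)),
    ("Mlkl", "up", "down", ("DENRG",)),
    ("Mefv", "up", "down", ("DEPRG",)),
    ("Il1rn", "up", "down", ("DEPRG",)),
    ("Anxa2", "up", "down", ("DEPRG",)),
    ("Ccr5", "up", "down", ("DEPRG",)),
]

# (network label, lncRNA, miRNA, mRNA) as listed per network
_AXIS_ROWS = [
    ("apoptosis", "Malat1", "miR-181a-5p", "Mapt"),
    ("apoptosis", "Malat1", "miR-181b-5p", "Mapt"),
    ("apoptosis", "Neat1", "miR-181a-5p", "Mapt"),
    ("apoptosis", "Neat1", "miR-181b-5p", "Mapt"),
    ("necroptosis", "Malat1", "miR-181a-5p", "Tnf"),
    ("necroptosis", "Neat1", "miR-181a-5p", "Tnf"),
    ("pyroptosis", "Malat1", "miR-181a-5p", "Tnf"),
    ("pyroptosis", "Malat1", "miR-181c-5p", "Tnf"),
]

_LABEL_TO_CATEGORY = {"DEARG": "apoptosis", "DENRG": "necroptosis",
                      "DEPRG": "pyroptosis"}


def paper_fixture_membership() -> MembershipTable:
    """The packaged 15-row DEG membership table (the worked example)."""
    rows = [
        MembershipRow(gene=gene,
                      directions={_DATASET_A: da, _DATASET_B: db},
                      categories=frozenset(cats))
        for gene, da, db, cats in _MEMBERSHIP_ROWS
    ]
    return MembershipTable(rows=rows, dataset_labels=(_DATASET_A, _DATASET_B))


def paper_fixture_axes() -> List[RegulatoryAxis]:
    """The eight listed regulatory axes, tagged with their network label."""
    return [RegulatoryAxis(lncrna=l, mirna=m, mrna=g, network=label)
            for label, l, m, g in _AXIS_ROWS]


def paper_fixture_pcd_sets() -> List[GeneSet]:
    """Per-category gene sets derived from the membership fixture.

    These are the fixture's category columns re-expressed as gene sets, so
    that running the membership construction on them reproduces the fixture.
    """
    sets = []
    for label, category in _LABEL_TO_CATEGORY.items():
        symbols = [gene for gene, _, _, cats in _MEMBERSHIP_ROWS if label in cats]
        sets.append(GeneSet.from_symbols(name=f"{category}_fixture",
                                         category=category,
                                         raw_symbols=symbols,
                                         provenance=["fixture"]))
    return sets


def paper_fixture_common_degs() -> Dict[str, Dict[str, str]]:
    """The fixture's genes with their per-dataset directions, in the shape
    produced by the cross-dataset intersection."""
    return {
        gene: {_DATASET_A: da, _DATASET_B: db}
        for gene, da, db, _ in _MEMBERSHIP_ROWS
    }


# ---------------------------------------------------------------------------
# writers

def write_gene_list(symbols: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(symbols) + "\n")


def write_axes_tsv(axes: Sequence[RegulatoryAxis], path) -> None:
    lines = ["network\tlncRNA\tmiRNA\tmRNA"]
    lines += [f"{a.network}\t{a.lncrna}\t{a.mirna}\t{a.mrna}" for a in axes]
    Path(path).write_text("\n".join(lines) + "\n")
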