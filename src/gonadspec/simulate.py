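"""Synthetic RNA-seq count data with planted tissue-specific genes.

The generator emulates the design of the gonad transcriptome study this
package implements: 3 ovary + 3 testis + 7 somatic libraries (optionally
extra developmental-stage libraries), overdispersed negative-binomial
counts, a configurable number of planted ovary- and testis-specific genes,
and one designated annotation term enriched among the planted genes.
Ground-truth labels are recorded so that classifier sensitivity and
false-positive rate can be measured.

Expected counts scale with gene length and nominal library size so that the
planted fold change lives on the RPKM scale the downstream classifier uses:
a gene with baseline_mean b, length L bp and nominal library size N has
expected count b * (L/1000) * (N/1e6) outside its target tissue, i.e. an
expected RPKM of roughly b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ConfigError, CountMatrix, InputError

#: The study's six somatic organs; outer and pallial mantle were sequenced
#: separately, giving seven somatic libraries.
SOMATIC_ORGANS = (
    "gill",
    "mantle_outer",
    "mantle_pallial",
    "adductor_muscle",
    "digestive_gland",
    "labial_palp",
    "hemocytes",
)

ENRICHED_GO_TERM = "GO:SIM0001"


@dataclass(frozen=True)
class SampleLayout:
    """Number of libraries per group; default mirrors the study design."""

    ovary: int = 3
    testis: int = 3
    somatic: int = 7
    stage: int = 0

    @property
    def n_samples(self) -> int:
        return self.ovary + self.testis + self.somatic + self.stage


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    effect_fold is the mean-expression multiplier of a planted gene in its
    target tissue relative to everywhere else; baseline_mean is the expected
    RPKM-scale expression outside the target tissue; dispersion is the
    negative-binomial size parameter r (variance m + m^2/r).
    """

    n_genes: int
    n_ovary_specific: int = 0
    n_testis_specific: int = 0
    effect_fold: float = 10.0
    baseline_mean: float = 20.0
    dispersion: float = 10.0
    library_sizes: list[int] | None = None
    layout: SampleLayout = field(default_factory=SampleLayout)
    length_range: tuple[int, int] = (500, 3000)
    n_terms: int = 50
    planted_term_fraction: float = 0.8
    background_term_rate: float = 0.05
    n_pathways: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigError("n_genes must be non-negative")
        if self.n_ovary_specific < 0 or self.n_testis_specific < 0:
            raise ConfigError("planted gene counts must be non-negative")
        if self.n_ovary_specific + self.n_testis_specific > self.n_genes:
            raise ConfigError("more planted genes than genes")
        if self.effect_fold < 1:
            raise ConfigError("effect_fold must be >= 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigError("baseline_mean and dispersion must be positive")
        if self.length_range[0] > self.length_range[1]:
            raise ConfigError(
                f"invalid length_range {self.length_range}: min > max"
            )
        if self.length_range[0] <= 0:
            raise ConfigError("gene lengths must be positive")
        if not 0 <= self.planted_term_fraction <= 1:
            raise ConfigError("planted_term_fraction must be in [0, 1]")
        if not 0 <= self.background_term_rate <= 1:
            raise ConfigError("background_term_rate must be in [0, 1]")
        if self.library_sizes is None:
            self.library_sizes = [5_000_000] * self.layout.n_samples
        if len(self.library_sizes) != self.layout.n_samples:
            raise ConfigError(
                f"{len(self.library_sizes)} library sizes for "
                f"{self.layout.n_samples} samples"
            )
        if any(n <= 0 for n in self.library_sizes):
            raise ConfigError("library sizes must be positive")


@dataclass
class GeneModel:
    """A synthetic gene: ID, exonic length, annotations, and truth label."""

    gene_id: str
    length_bp: int
    go_terms: tuple[str, ...]
    kegg_pathways: tuple[str, ...]
    truth_label: str  # "ovary_specific", "testis_specific" or "background"


@dataclass
class GroundTruth:
    """Planted-gene labels and the designated enriched term."""

    labels: pd.Series  # gene_id -> label
    enriched_term: str

    def genes_with_label(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()


def sample_table(layout: SampleLayout) -> pd.DataFrame:
    """Sample metadata (group, label) for a layout, in fixed order."""
    rows = []
    for i in range(layout.ovary):
        rows.append((f"OV{i + 1}", "ovary", f"ovary_{i + 1}"))
    for i in range(layout.testis):
        rows.append((f"TE{i + 1}", "testis", f"testis_{i + 1}"))
    for i in range(layout.somatic):
        organ = SOMATIC_ORGANS[i] if i < len(SOMATIC_ORGANS) else f"organ_{i + 1}"
        rows.append((f"SO{i + 1}", "somatic", organ))
    for i in range(layout.stage):
        rows.append((f"ST{i + 1}", "stage", f"stage_{i + 1}"))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "label"])
    return df.set_index("sample_id")


def generate_gene_models(config: SimConfig) -> list[GeneModel]:
    """Draw gene lengths, truth labels, and annotation terms.

    Truth labels are assigned to a random subset of genes; the designated
    enriched GO term covers ``planted_term_fraction`` of the planted genes
    and ``background_term_rate`` of the rest.  Every other term annotates
    genes independently at the background rate, as do KEGG pathways.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    if n == 0:
        return []
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, size=n)

    labels = np.array(["background"] * n, dtype=object)
    planted = rng.choice(n, size=config.n_ovary_specific + config.n_testis_specific, replace=False)
    labels[planted[: config.n_ovary_specific]] = "ovary_specific"
    labels[planted[config.n_ovary_specific:]] = "testis_specific"

    is_planted = labels != "background"
    has_enriched = np.where(
        is_planted,
        rng.random(n) < config.planted_term_fraction,
        rng.random(n) < config.background_term_rate,
    )
    go_ids = [ENRICHED_GO_TERM] + [f"GO:SIM{i + 2:04d}" for i in range(config.n_terms - 1)]
    other_go = rng.random((n, max(config.n_terms - 1, 0))) < config.background_term_rate
    kegg_ids = [f"ko:SIM{i + 1:03d}" for i in range(config.n_pathways)]
    kegg_hits = rng.random((n, config.n_pathways)) < config.background_term_rate

    models = []
    for i in range(n):
        go = tuple(
            ([ENRICHED_GO_TERM] if has_enriched[i] else [])
            + [go_ids[j + 1] for j in np.flatnonzero(other_go[i])]
        )
        kegg = tuple(kegg_ids[j] for j in np.flatnonzero(kegg_hits[i]))
        models.append(
            GeneModel(
                gene_id=f"Cg{i + 1:05d}",
                length_bp=int(lengths[i]),
                go_terms=go,
                kegg_pathways=kegg,
                truth_label=str(labels[i]),
            )
        )
    return models


def plant_signal(
    models: list[GeneModel], config: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Build the genes x samples matrix of expected counts.

    A gene labeled ovary_specific has expected count effect_fold times its
    non-ovary expectation in every ovary sample (symmetrically for testis);
    background genes and all developmental-stage columns get
    tissue-independent baseline means.  Means scale with gene length (per
    kilobase) and nominal library size (per million reads).
    """
    if not models:
        raise InputError("plant_signal requires a nonempty gene-model list")
    samples = sample_table(config.layout)
    lengths = np.array([m.length_bp for m in models], dtype=float)
    lib = np.asarray(config.library_sizes, dtype=float)

    base = config.baseline_mean * (lengths[:, None] / 1e3) * (lib[None, :] / 1e6)
    fold = np.ones((len(models), len(samples)))
    group = samples["group"].to_numpy()
    labels = pd.Series(
        [m.truth_label for m in models],
        index=pd.Index([m.gene_id for m in models], name="gene_id"),
    )
    fold[np.asarray(labels == "ovary_specific")[:, None] & (group == "ovary")[None, :]] = config.effect_fold
    fold[np.asarray(labels == "testis_specific")[:, None] & (group == "testis")[None, :]] = config.effect_fold

    mean_matrix = pd.DataFrame(
        base * fold, index=labels.index, columns=samples.index.rename(None)
    )
    return mean_matrix, GroundTruth(labels=labels, enriched_term=ENRICHED_GO_TERM)


def simulate_counts(
    mean_matrix: pd.DataFrame, dispersion: float, seed: int
) -> CountMatrix:
    """Draw independent negative-binomial counts around a mean matrix.

    Parameterised by mean m and size r (= ``dispersion``), so the variance
    is m + m^2/r; m = 0 yields a count of 0.  Per-sample library sizes are
    recorded as the realised column totals.
    """
    means = mean_matrix.to_numpy(dtype=float)
    if (means < 0).any():
        raise InputError("negative mean in mean matrix")
    if dispersion <= 0:
        raise InputError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    # p = r / (r + m); m = 0 gives p = 1 hence a certain zero.
    p = dispersion / (dispersion + means)
    counts = rng.negative_binomial(dispersion, p)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=mean_matrix.index, columns=mean_matrix.columns)
    )


def simulate_dataset(
    config: SimConfig,
) -> tuple[CountMatrix, list[GeneModel], pd.DataFrame, GroundTruth]:
    """Generate one complete dataset: counts, models, metadata, truth."""
    models = generate_gene_models(config)
    if not models:
        samples = sample_table(config.layout)
        counts = CountMatrix(
            counts=pd.DataFrame(
                np.zeros((0, len(samples)), dtype=int),
                index=pd.Index([], name="gene_id"),
                columns=samples.index,
            ),
            library_size=pd.Series(1.0, index=samples.index),
        )
        truth = GroundTruth(labels=pd.Series(dtype=object), enriched_term=ENRICHED_GO_TERM)
        return counts, models, samples, truth
    mean_matrix, truth = plant_signal(models, config)
    counts = simulate_counts(mean_matrix, config.dispersion, seed=config.seed + 1)
    return counts, models, sample_table(config.layout), truth


def models_to_frame(models: list[GeneModel]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "length_bp": [m.length_bp for m in models],
            "go_terms": [";".join(m.go_terms) for m in models],
            "kegg_pathways": [";".join(m.kegg_pathways) for m in models],
        }
    )
    return df.set_index("gene_id")


def term_map_from_models(models: list[GeneModel], namespace: str = "go") -> dict[str, set[str]]:
    """gene -> annotation-term mapping, for the enrichment engine."""
    attr = {"go": "go_terms", "kegg": "kegg_pathways"}[namespace]
    return {m.gene_id: set(getattr(m, attr)) for m in models if getattr(m, attr)}


def write_dataset(
    counts: CountMatrix,
    models: list[GeneModel],
    metadata: pd.DataFrame,
    truth: GroundTruth,
    out_dir,
) -> dict[str, str]:
    """Write the dataset as plain TSV files readable by :mod:`gonadspec.io`.

    Emits counts.tsv, gene_models.tsv, samples.tsv, go_map.tsv,
    kegg_map.tsv and truth.tsv; returns the path of each.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model_ids = [m.gene_id for m in models]
    if list(counts.counts.index) != model_ids or list(truth.labels.index) != model_ids:
        raise InputError("counts, models and truth must list the same genes in order")
    if list(counts.counts.columns) != list(metadata.index):
        raise InputError("count columns and metadata rows must match in order")

    paths = {}
    paths["counts"] = str(out / "counts.tsv")
    counts.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    paths["models"] = str(out / "gene_models.tsv")
    models_to_frame(models).to_csv(paths["models"], sep="\t")
    paths["metadata"] = str(out / "samples.tsv")
    metadata.rename_axis("sample_id").to_csv(paths["metadata"], sep="\t")

    for ns, fname in (("go", "go_map.tsv"), ("kegg", "kegg_map.tsv")):
        rows = []
        for m in models:
            for term in getattr(m, {"go": "go_terms", "kegg": "kegg_pathways"}[ns]):
                rows.append((m.gene_id, term))
        path = out / fname
        pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)
        paths[f"{ns}_map"] = str(path)

    paths["truth"] = str(out / "truth.tsv")
    truth.labels.rename("label").rename_axis("gene_id").to_csv(paths["truth"], sep="\t")
    return paths
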