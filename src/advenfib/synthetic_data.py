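"""Synthetic data generators for the adventitial-fibroblast pipeline.

Every downstream stage (QC, mesenchymal selection, marker discovery,
signature scoring, gene-set enrichment, trait association) can be exercised
on data produced here, with full ground truth: cell types, planted marker
panels, branching expression programs, doublets, mitochondrial outliers,
planted gene--trait correlations and planted gene-set overlaps.

Count model
-----------
UMI counts follow a negative binomial (gamma--Poisson) law per gene: the
per-gene base mean is a log-normal draw scaled to ``nb_mean``, and a shared
dispersion ``nb_dispersion`` (theta; variance = mu + mu^2/theta) controls
overdispersion.  This is the standard noise model for droplet scRNA-seq
counts; the real study's data-generating process is of course unknown, so
every distributional choice here is a stand-in with known ground truth.

Planted structure
-----------------
* a fibroblast / mural-cell mixture in configurable proportions, with a
  pan-mesenchymal gate gene (*Pdgfrb*) expressed in both types;
* a panel of fibroblast markers whose mean is elevated by
  ``2**logfc_markers`` in fibroblasts;
* ``n_branches`` branching differentiation programs: each fibroblast gets a
  branch and a position u in [0, 1], and the branch's program genes ramp
  linearly in log-mean from base (u = 0) to ``+logfc_branch`` (u = 1);
* a shared origin program that decays along every branch (high at u = 0),
  so trajectory-origin inference has a recoverable signal;
* doublets: flagged barcodes receive the sum of their own draw and a draw
  from a second, uniformly sampled cell profile, pushing their UMI total
  above the doublet threshold when singlet totals sit below it;
* mitochondrial content: designated outlier cells have their mito-gene
  means inflated to an expected mito fraction of 0.25 (> the 0.15 QC cut),
  all other cells sit at 0.05;
* optional contamination: a fraction of cells express the absence markers
  (Cd68, Pecam1, Rbfox3, Adipoq) used by the purity check.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .trait_association import BulkTraitDataset

GATE_GENE = "Pdgfrb"
ABSENCE_MARKERS = ("Cd68", "Pecam1", "Rbfox3", "Adipoq")

MITO_TARGET_NORMAL = 0.05
MITO_TARGET_OUTLIER = 0.25


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of the single-cell count simulation.

    Defaults emulate a sorted adventitial mesenchymal preparation:
    ~3000 cells, 2000 genes, two-thirds fibroblasts, three branching
    fibroblast programs, and singlet UMI totals (~ n_genes * nb_mean =
    10 000) below the 15 000-UMI doublet cut while doublet totals
    (~20 000) land above it.
    """

    n_cells: int = 3000
    n_genes: int = 2000
    cell_type_props: dict[str, float] = field(
        default_factory=lambda: {"fibroblast": 2 / 3, "mural": 1 / 3}
    )
    n_branches: int = 3
    branch_program_size: int = 30
    marker_panel_size: int = 12
    n_active_markers: int | None = None  # None: whole panel elevated
    origin_program_size: int = 30
    nb_mean: float = 5.0
    nb_dispersion: float = 2.0
    mito_gene_count: int = 10
    mito_fraction_outlier_rate: float = 0.03
    doublet_rate: float = 0.03
    contamination_rate: float = 0.0
    logfc_markers: float = 2.0
    logfc_branch: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        props = self.cell_type_props
        if abs(sum(props.values()) - 1.0) > 1e-8:
            raise ValueError(f"cell_type_props must sum to 1, got {sum(props.values())}")
        if set(props) != {"fibroblast", "mural"}:
            raise ValueError("cell_type_props must have keys 'fibroblast' and 'mural'")
        for name in ("n_cells", "n_genes", "nb_mean", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_active_markers is not None and not (
            0 <= self.n_active_markers <= self.marker_panel_size
        ):
            raise ValueError("n_active_markers must be within the marker panel size")
        for name in ("mito_fraction_outlier_rate", "doublet_rate", "contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        n_special = (
            self.mito_gene_count
            + 1  # gate gene
            + len(ABSENCE_MARKERS)
            + self.marker_panel_size
            + self.n_branches * self.branch_program_size
            + self.origin_program_size
        )
        if n_special > self.n_genes:
            raise ValueError(
                f"planted genes ({n_special}) exceed n_genes ({self.n_genes}); "
                "reduce panel/program sizes or increase n_genes"
            )


@dataclass
class GroundTruth:
    """Everything the generator knows about the cells and genes it made.

    ``cells`` is indexed by barcode with columns ``cell_type``, ``branch``
    (nullable int), ``position`` (NaN for mural cells), ``is_doublet``,
    ``is_mito_outlier``.
    """

    cells: pd.DataFrame
    marker_genes: list[str]
    branch_programs: dict[int, list[str]]
    origin_program: list[str]
    mito_genes: list[str]

    def __post_init__(self) -> None:
        pos = self.cells["position"].dropna()
        if len(pos) and not ((pos >= 0) & (pos <= 1)).all():
            raise ValueError("branch positions must lie in [0, 1]")


@dataclass(frozen=True)
class BulkSimConfig:
    """Parameters of the bulk plaque-segment expression/trait simulation.

    The defaults emulate the human validation cohort: 43 carotid plaque
    segments, three trajectory gene sets of 46, 32 and 23 genes, and three
    histology traits.  Each trait t has a latent per-segment factor z_t;
    the trait column IS z_t and a planted gene in set s is
    ``baseline + sum_t lambda[s, t] * z_t + noise_sd * eps``, so the
    population Pearson correlation of a planted gene with trait t is
    ``lambda[s, t] / sqrt(sum_t lambda[s, t]^2 + noise_sd^2)`` in closed
    form.  By default set 3 loads negatively (mirroring a gene set that
    anticorrelates with detrimental plaque traits) and sets 1-2 positively,
    each on its own trait at target |r| = 0.5.
    """

    n_segments: int = 43
    n_genes: int = 500
    n_traits: int = 3
    planted_set_sizes: tuple[int, ...] = (46, 32, 23)
    planted_effect: np.ndarray | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def effect_matrix(self) -> np.ndarray:
        """Resolve ``planted_effect`` to a (n_sets, n_traits) loading array."""
        n_sets = len(self.planted_set_sizes)
        if self.planted_effect is not None:
            lam = np.asarray(self.planted_effect, dtype=float)
            if lam.shape != (n_sets, self.n_traits):
                raise ValueError(
                    f"planted_effect must have shape ({n_sets}, {self.n_traits}), "
                    f"got {lam.shape}"
                )
            return lam
        lam = np.zeros((n_sets, self.n_traits))
        base = loading_for_target_r(0.5, self.noise_sd)
        for s in range(n_sets):
            t = s % self.n_traits
            sign = -1.0 if s == n_sets - 1 else 1.0
            lam[s, t] = sign * base
        return lam

    def validate(self) -> None:
        if self.n_segments < 3:
            raise ValueError("n_segments must be >= 3 (correlation undefined below)")
        if any(s <= 0 for s in self.planted_set_sizes):
            raise ValueError("planted set sizes must be positive")
        if sum(self.planted_set_sizes) > self.n_genes:
            raise ValueError("planted sets exceed n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lam = self.effect_matrix()
        denom = np.sqrt((lam**2).sum(axis=1) + self.noise_sd**2)
        if np.any(denom == 0):
            raise ValueError("zero-variance planted genes: increase noise_sd or loadings")


def loading_for_target_r(r: float, noise_sd: float) -> float:
    """Latent-factor loading giving population correlation ``r`` for a gene
    loading on a single trait with residual sd ``noise_sd``.

    Inverts r = lambda / sqrt(lambda^2 + noise_sd^2).
    """
    if not -1.0 < r < 1.0:
        raise ValueError("target r must lie in (-1, 1)")
    return r * noise_sd / np.sqrt(1.0 - r * r)


# ---------------------------------------------------------------------------
# single-cell generator
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma–Poisson draw: NB with mean ``mean`` and dispersion ``theta``."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 0.0) / theta)
    return rng.poisson(lam)


def simulate_sc_dataset(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a fibroblast/mural UMI count matrix with known structure.

    Returns an AnnData (cells x genes, sparse integer counts,
    ``var['is_mito']`` flagged) and the :class:`GroundTruth` describing
    every planted feature.  Bit-reproducible for a fixed config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_cells, n_genes = config.n_cells, config.n_genes
    theta = config.nb_dispersion

    # --- gene layout: special genes first, background after
    mito_genes = [f"mt-Nd{i}" for i in range(config.mito_gene_count)]
    names: list[str] = list(mito_genes) + [GATE_GENE] + list(ABSENCE_MARKERS)
    marker_genes = [f"Fibmk{i}" for i in range(config.marker_panel_size)]
    names += marker_genes
    branch_programs: dict[int, list[str]] = {}
    for b in range(config.n_branches):
        branch_programs[b] = [f"Br{b}g{i}" for i in range(config.branch_program_size)]
        names += branch_programs[b]
    origin_program = [f"Orig{i}" for i in range(config.origin_program_size)]
    names += origin_program
    names += [f"Gene{i:05d}" for i in range(n_genes - len(names))]
    gene_index = {g: j for j, g in enumerate(names)}
    mito_idx = np.array([gene_index[g] for g in mito_genes], dtype=int)
    nonmito_mask = np.ones(n_genes, dtype=bool)
    nonmito_mask[mito_idx] = False

    # --- per-gene base means: log-normal scaled to nb_mean
    sigma = 1.0
    base = config.nb_mean * np.exp(rng.normal(0.0, sigma, n_genes) - sigma**2 / 2)
    base[[gene_index[g] for g in ABSENCE_MARKERS]] = 0.0
    base[gene_index[GATE_GENE]] = config.nb_mean

    # --- cells
    n_fib = int(round(config.cell_type_props["fibroblast"] * n_cells))
    cell_type = np.array(["fibroblast"] * n_fib + ["mural"] * (n_cells - n_fib))
    rng.shuffle(cell_type)
    is_fib = cell_type == "fibroblast"
    branch = np.full(n_cells, -1)
    position = np.full(n_cells, np.nan)
    fib_idx = np.flatnonzero(is_fib)
    if config.n_branches > 0:
        branch[fib_idx] = rng.integers(0, config.n_branches, size=fib_idx.size)
        position[fib_idx] = rng.uniform(0.0, 1.0, size=fib_idx.size)

    is_doublet = rng.random(n_cells) < config.doublet_rate
    is_mito_outlier = rng.random(n_cells) < config.mito_fraction_outlier_rate
    contaminated = {
        m: rng.random(n_cells) < config.contamination_rate for m in ABSENCE_MARKERS
    }

    # --- per-cell mean matrix (dense; sizes here are modest)
    mean = np.tile(base, (n_cells, 1))
    n_active = (
        config.marker_panel_size
        if config.n_active_markers is None
        else config.n_active_markers
    )
    mk_idx = np.array([gene_index[g] for g in marker_genes[:n_active]], dtype=int)
    if mk_idx.size:
        mean[np.ix_(is_fib, mk_idx)] *= 2.0**config.logfc_markers
    for b, genes in branch_programs.items():
        gidx = np.array([gene_index[g] for g in genes], dtype=int)
        on = is_fib & (branch == b)
        if gidx.size and on.any():
            mean[np.ix_(on, gidx)] *= 2.0 ** (config.logfc_branch * position[on])[:, None]
    og_idx = np.array([gene_index[g] for g in origin_program], dtype=int)
    if og_idx.size and fib_idx.size and config.n_branches > 0:
        decay = 2.0 ** (config.logfc_branch * (1.0 - position[fib_idx]))
        mean[np.ix_(is_fib, og_idx)] *= decay[:, None]
    for m, mask in contaminated.items():
        if mask.any():
            mean[mask, gene_index[m]] = 2.0 * config.nb_mean

    # --- mitochondrial content: repartition each cell's expected total so the
    # mito fraction hits its target without inflating the UMI total (which
    # would confound the doublet rule)
    mito_target = np.where(is_mito_outlier, MITO_TARGET_OUTLIER, MITO_TARGET_NORMAL)
    nonmito_total = mean[:, nonmito_mask].sum(axis=1)
    cell_total = nonmito_total / (1.0 - MITO_TARGET_NORMAL)
    mean[:, nonmito_mask] *= ((1.0 - mito_target) * cell_total / nonmito_total)[:, None]
    mito_profile = rng.dirichlet(np.full(config.mito_gene_count, 5.0))
    mean[:, mito_idx] = (mito_target * cell_total)[:, None] * mito_profile[None, :]

    # --- draw counts; doublets add a second, uniformly sampled profile
    counts = _nb_draw(rng, mean, theta)
    dbl_idx = np.flatnonzero(is_doublet)
    if dbl_idx.size:
        partners = rng.integers(0, n_cells, size=dbl_idx.size)
        counts[dbl_idx] += _nb_draw(rng, mean[partners], theta)

    barcodes = [f"CELL{i:05d}" for i in range(n_cells)]
    cells = pd.DataFrame(
        {
            "cell_type": cell_type,
            "branch": pd.array(np.where(branch >= 0, branch, pd.NA), dtype="Int64"),
            "position": position,
            "is_doublet": is_doublet,
            "is_mito_outlier": is_mito_outlier,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    truth = GroundTruth(
        cells=cells,
        marker_genes=marker_genes,
        branch_programs=branch_programs,
        origin_program=origin_program,
        mito_genes=mito_genes,
    )
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.int32)),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(
            {"is_mito": [g in set(mito_genes) for g in names]},
            index=pd.Index(names, name="gene"),
        ),
    )
    return adata, truth


# ---------------------------------------------------------------------------
# bulk plaque-segment generator
# ---------------------------------------------------------------------------

def simulate_bulk_trait_dataset(
    config: BulkSimConfig,
) -> tuple[BulkTraitDataset, dict[str, list[str]]]:
    """Simulate segments x genes expression and segments x traits tables.

    Returns the dataset plus the planted gene sets, keyed ``set_1`` ...;
    genes outside every planted set are pure noise (expected correlation 0
    with every trait).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_seg, n_genes, n_traits = config.n_segments, config.n_genes, config.n_traits
    lam = config.effect_matrix()

    z = rng.standard_normal((n_seg, n_traits))  # latent per-segment factors
    genes = [f"BGene{i:04d}" for i in range(n_genes)]
    baseline = rng.normal(8.0, 1.0, n_genes)  # log-scale abundance offsets
    expr = baseline[None, :] + config.noise_sd * rng.standard_normal((n_seg, n_genes))

    planted: dict[str, list[str]] = {}
    start = 0
    for s, size in enumerate(config.planted_set_sizes):
        members = genes[start : start + size]
        planted[f"set_{s + 1}"] = members
        expr[:, start : start + size] += (z @ lam[s])[:, None]
        start += size

    segments = [f"SEG{i:03d}" for i in range(n_seg)]
    traits = [f"trait_{t + 1}" for t in range(n_traits)]
    data = BulkTraitDataset(
        expression=pd.DataFrame(expr, index=segments, columns=genes),
        traits=pd.DataFrame(z, index=segments, columns=traits),
    )
    return data, planted


# ---------------------------------------------------------------------------
# gene universe / GWAS-overlap generator
# ---------------------------------------------------------------------------

@dataclass
class GeneUniverse:
    """A synthetic enrichment scenario with exactly known overlap.

    ``universe`` and ``target`` hold human symbols; ``test_set`` holds mouse
    symbols whose one-to-one orthologs realise the planted overlap with the
    target list.
    """

    universe: list[str]
    target: list[str]
    test_set: list[str]
    ortholog_map: pd.DataFrame  # columns: mouse_symbol, human_symbol


def simulate_gene_universe(
    n_universe: int,
    n_target: int,
    n_set: int,
    planted_overlap: int,
    seed: int = 0,
    ortholog_fraction: float = 1.0,
) -> GeneUniverse:
    """Build a universe, a target list (e.g. GWAS CAD genes), and a query set
    overlapping the target in exactly ``planted_overlap`` genes after
    ortholog mapping.
    """
    if not 0 <= planted_overlap <= min(n_target, n_set):
        raise ValueError("planted_overlap must satisfy 0 <= k <= min(n_target, n_set)")
    if max(n_target, n_set) > n_universe:
        raise ValueError("target and set sizes must not exceed the universe")
    if not 0.0 < ortholog_fraction <= 1.0:
        raise ValueError("ortholog_fraction must be in (0, 1]")

    rng = np.random.default_rng(seed)
    human = [f"HGENE{i:04d}" for i in range(n_universe)]
    n_mapped = int(round(ortholog_fraction * n_universe))
    if n_set > n_mapped or n_target > n_mapped:
        raise ValueError("ortholog coverage too low for the requested set sizes")
    mapped = list(rng.choice(n_universe, size=n_mapped, replace=False))
    mouse_of = {human[i]: f"Mgene{i:04d}" for i in mapped}

    # target drawn from the mapped region so the planted overlap is feasible
    target_idx = rng.choice(mapped, size=n_target, replace=False)
    target = [human[i] for i in target_idx]
    off_target = [i for i in mapped if i not in set(target_idx)]
    if n_set - planted_overlap > len(off_target):
        raise ValueError("universe too small for the requested off-target set size")
    in_part = rng.choice(target_idx, size=planted_overlap, replace=False)
    out_part = rng.choice(off_target, size=n_set - planted_overlap, replace=False)
    test_set = [mouse_of[human[i]] for i in list(in_part) + list(out_part)]

    omap = pd.DataFrame(
        {
            "mouse_symbol": [mouse_of[human[i]] for i in mapped],
            "human_symbol": [human[i] for i in mapped],
        }
    )
    return GeneUniverse(universe=human, target=target, test_set=test_set, ortholog_map=omap)
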