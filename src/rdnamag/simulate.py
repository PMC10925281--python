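"""Synthetic data generators with recorded ground truth.

``simulate_experiment`` emulates a 10x-style testis single-cell experiment
run once per rDNA copy-number condition: five cell types (GSC, SG,
spermatocyte, spermatid, cyst) with marker programs over the canonical
testis panel (vas, nos, ovo, tj, zfh1, dlg1, CadN, fzo, CycB, CG32106,
m-cup), negative-binomial counts with lognormal library sizes, planted
condition effects, per-condition ambient contamination, GSC:cyst doublets,
and library-size QC outliers. Every planted feature is recorded in a
:class:`SyntheticTruth` so each downstream stage of the discovery pipeline
can be scored without any external dataset.

``simulate_ddpcr`` and ``simulate_cross`` generate droplet-digital-PCR wells
and magnification-cross offspring counts from their exact binomial sampling
models, serving as oracles for the estimators that invert them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    CONDITIONS,
    LOW_RDNA,
    NORMAL_RDNA,
    GeneExpressionMatrix,
    ValidationError,
)
from .ddpcr import DdpcrWell

CELL_TYPES = ("GSC", "SG", "spermatocyte", "spermatid", "cyst")

_NAMED_MARKERS = {
    "GSC": {"nos": 40.0, "ovo": 40.0},
    "SG": {},
    "cyst": {"dlg1": 40.0, "CadN": 40.0, "tj": 40.0, "zfh1": 40.0},
    "spermatocyte": {"fzo": 40.0, "CycB": 40.0},
    "spermatid": {"CG32106": 40.0, "m-cup": 40.0},
}


def default_marker_programs(n_program_genes: int = 15, program_fold: float = 12.0,
                            artifact_genes=(), artifact_fold: float = 256.0) -> dict:
    """Named markers plus ``n_program_genes`` anonymous program genes per type.

    Real cell types differ across many genes beyond the canonical markers;
    the extra program genes give each type a separable transcriptional
    identity. Ambient-artifact bait genes join the spermatocyte program at a
    high fold so their expression dominates the soup.
    """
    programs = {}
    for ctype in CELL_TYPES:
        prog = dict(_NAMED_MARKERS[ctype])
        for i in range(n_program_genes):
            prog[f"prog_{ctype}_{i + 1:02d}"] = program_fold
        programs[ctype] = prog
    for g in artifact_genes:
        programs["spermatocyte"][g] = artifact_fold
    return programs


@dataclass(frozen=True)
class PlantedEffect:
    """A condition effect planted on one gene in one or more cell types.

    ``log2fc`` is the log2 fold-change of the low-rDNA condition over the
    normal condition, applied to the gene's mean in the listed cell types.
    """

    gene: str
    cell_types: tuple
    log2fc: float

    @property
    def category(self) -> str:
        germline = set(self.cell_types) & {"GSC", "SG"}
        if not germline:
            return "artifact"
        shared = "shared_" if germline == {"GSC", "SG"} else "gsc_"
        return shared + ("up" if self.log2fc > 0 else "down")


def default_planted_effects() -> list:
    """Default planted truth: 30 GSC-down, 20 GSC-up, 20 shared GSC+SG
    (10 down / 10 up), 10 spermatocyte ambient-artifact genes, all |log2FC|=1."""
    effects = []
    idx = 1

    def take(n):
        nonlocal idx
        names = [f"gene{j:04d}" for j in range(idx, idx + n)]
        idx += n
        return names

    effects += [PlantedEffect(g, ("GSC",), -1.0) for g in take(30)]
    effects += [PlantedEffect(g, ("GSC",), +1.0) for g in take(20)]
    effects += [PlantedEffect(g, ("GSC", "SG"), -1.0) for g in take(10)]
    effects += [PlantedEffect(g, ("GSC", "SG"), +1.0) for g in take(10)]
    effects += [PlantedEffect(g, ("spermatocyte",), +1.0) for g in take(10)]
    return effects


def _default_cells() -> dict:
    return {"GSC": 600, "SG": 400, "spermatocyte": 300, "spermatid": 300, "cyst": 400}


def _default_shared_programs() -> list:
    # vas marks the whole early germline (GSC and SG alike)
    return [{"genes": {"vas": 40.0}, "types": ("GSC", "SG")}]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment; defaults are the study
    conditions every end-to-end test and the acceptance run use."""

    n_genes: int = 2000
    n_cells_per_type_per_condition: dict = field(default_factory=_default_cells)
    baseline_mean: float = 6.0              # mean expected counts per background gene
    gene_abundance_sigma: float = 1.2       # lognormal spread of background gene means
    marker_baseline: float = 0.25           # marker/program gene mean outside its type
    marker_scale: float = 0.25              # on-type program mean = fold * marker_scale
    planted_gene_mean: float = 4.0          # base mean of genes carrying planted effects
    nb_dispersion: float = 10.0             # NB variance = mu + mu^2 / dispersion
    library_mu: float = 0.0                 # lognormal library-size factor
    library_sigma: float = 0.3
    marker_programs: dict = None            # type -> {gene: fold}; default built below
    shared_programs: list = field(default_factory=_default_shared_programs)
    planted_effects: list = field(default_factory=default_planted_effects)
    ambient_fraction: float = 0.05          # rho
    doublet_rate: float = 0.05              # delta, fraction of output barcodes
    qc_outlier_rate: float = 0.02
    qc_window: tuple = (5500, 250000)       # library-size window outliers are pushed out of
    seed: int = 0

    def __post_init__(self):
        if self.marker_programs is None:
            artifact = [e.gene for e in self.planted_effects if e.category == "artifact"]
            self.marker_programs = default_marker_programs(artifact_genes=artifact)
        self.validate()

    def validate(self):
        if self.ambient_fraction + self.doublet_rate >= 1:
            raise ValidationError("ambient_fraction + doublet_rate must be < 1")
        for frac in (self.ambient_fraction, self.doublet_rate, self.qc_outlier_rate):
            if not 0 <= frac < 1:
                raise ValidationError("rates must lie in [0, 1)")
        seen = {}
        for ctype, prog in self.marker_programs.items():
            if ctype not in CELL_TYPES:
                raise ValidationError(f"unknown cell type in marker_programs: {ctype!r}")
            for gene, fold in prog.items():
                if fold <= 0:
                    raise ValidationError(f"fold for {gene!r} must be > 0")
                if gene in seen:
                    raise ValidationError(
                        f"marker {gene!r} appears in both {seen[gene]!r} and {ctype!r}; "
                        "per-type marker programs must be disjoint (use shared_programs)"
                    )
                seen[gene] = ctype
        for sprog in self.shared_programs:
            for fold in sprog["genes"].values():
                if fold <= 0:
                    raise ValidationError("shared program folds must be > 0")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        _build_gene_list(self)  # planted genes / programs fit in n_genes
        return self


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for scoring downstream stages."""

    cells: pd.DataFrame            # index barcode: cell_type, condition, is_doublet, source_types, qc_outlier
    planted: pd.DataFrame          # gene, cell_types, log2fc, category
    ambient_profile: pd.DataFrame  # per-gene soup proportions, one column per condition

    @property
    def doublet_barcodes(self) -> set:
        return set(self.cells.index[self.cells["is_doublet"]])

    @property
    def singlet_barcodes(self) -> set:
        return set(self.cells.index[~self.cells["is_doublet"]])

    def barcodes_of_type(self, cell_type: str, singlets_only: bool = True) -> set:
        mask = self.cells["cell_type"] == cell_type
        if singlets_only:
            mask &= ~self.cells["is_doublet"]
        return set(self.cells.index[mask])

    @property
    def gsc_specific_genes(self) -> set:
        """Genes with a planted effect in GSCs only — the discovery target."""
        return set(self.planted.loc[self.planted["category"].isin(["gsc_up", "gsc_down"]), "gene"])

    def genes_of_category(self, category: str) -> set:
        return set(self.planted.loc[self.planted["category"] == category, "gene"])


def _build_gene_list(config: SimulationConfig) -> list:
    program_genes = []
    for ctype in CELL_TYPES:
        for g in config.marker_programs.get(ctype, {}):
            if g not in program_genes:
                program_genes.append(g)
    for sprog in config.shared_programs:
        for g in sprog["genes"]:
            if g not in program_genes:
                program_genes.append(g)
    genes = list(program_genes)
    i = 1
    while len(genes) < config.n_genes:
        name = f"gene{i:04d}"
        if name not in program_genes:
            genes.append(name)
        i += 1
    if len(genes) > config.n_genes:
        raise ValidationError(
            f"n_genes={config.n_genes} is too small for "
            f"{len(program_genes)} marker/program genes"
        )
    for eff in config.planted_effects:
        if eff.gene not in genes:
            raise ValidationError(f"planted gene {eff.gene!r} not in the simulated gene set")
        for t in eff.cell_types:
            if t not in CELL_TYPES:
                raise ValidationError(f"planted effect on unknown cell type {t!r}")
    return genes


def _type_condition_means(config: SimulationConfig, genes: list, rng) -> dict:
    """Expected counts per gene for each (cell_type, condition), library factor 1."""
    gene_pos = {g: i for i, g in enumerate(genes)}
    program_genes = set()
    for prog in config.marker_programs.values():
        program_genes |= set(prog)
    for sprog in config.shared_programs:
        program_genes |= set(sprog["genes"])
    planted_genes = {e.gene for e in config.planted_effects}

    base = np.empty(len(genes))
    filler_idx = []
    for i, g in enumerate(genes):
        if g in program_genes:
            base[i] = config.marker_baseline
        elif g in planted_genes:
            base[i] = config.planted_gene_mean
        else:
            filler_idx.append(i)
    if filler_idx:
        weights = rng.lognormal(0.0, config.gene_abundance_sigma, size=len(filler_idx))
        weights *= config.baseline_mean * len(filler_idx) / weights.sum()
        base[filler_idx] = weights

    means = {}
    for ctype in CELL_TYPES:
        vec = base.copy()
        for gene, fold in config.marker_programs.get(ctype, {}).items():
            vec[gene_pos[gene]] = fold * config.marker_scale
        for sprog in config.shared_programs:
            if ctype in sprog["types"]:
                for gene, fold in sprog["genes"].items():
                    vec[gene_pos[gene]] = fold * config.marker_scale
        for cond in CONDITIONS:
            cvec = vec.copy()
            if cond == LOW_RDNA:
                for eff in config.planted_effects:
                    if ctype in eff.cell_types:
                        cvec[gene_pos[eff.gene]] *= 2.0 ** eff.log2fc
            means[(ctype, cond)] = cvec
    return means


def _nb_counts(mean_matrix: np.ndarray, dispersion: float, rng) -> np.ndarray:
    """Gamma-Poisson draw: variance = mu + mu^2 / dispersion."""
    lam = rng.gamma(shape=dispersion, scale=mean_matrix / dispersion)
    return rng.poisson(lam)


def simulate_experiment(config: SimulationConfig = None, seed: int = None):
    """Generate a synthetic two-condition experiment.

    Returns ``(matrix, truth)`` where ``matrix`` is a
    :class:`GeneExpressionMatrix` with per-cell ``condition`` metadata and
    ``truth`` a :class:`SyntheticTruth`.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    genes = _build_gene_list(config)
    means = _type_condition_means(config, genes, rng)
    rho, delta = config.ambient_fraction, config.doublet_rate
    qc_lo, qc_hi = config.qc_window

    columns, meta_rows = [], []
    for cond in CONDITIONS:
        cell_types, libs = [], []
        for ctype in CELL_TYPES:
            n = int(config.n_cells_per_type_per_condition.get(ctype, 0))
            cell_types += [ctype] * n
            libs.append(rng.lognormal(config.library_mu, config.library_sigma, size=n))
        libs = np.concatenate(libs) if libs else np.empty(0)
        n_singlets = len(cell_types)

        # per-cell expected profiles before ambient mixing
        M = np.stack([means[(t, cond)] for t in cell_types], axis=1) * libs

        # QC outliers: force expected library size outside the QC window
        n_out = int(round(config.qc_outlier_rate * n_singlets))
        outlier_idx = rng.choice(n_singlets, size=n_out, replace=False) if n_out else np.empty(0, int)
        qc_outlier = np.zeros(n_singlets, dtype=bool)
        for j, c in enumerate(outlier_idx):
            total = M[:, c].sum()
            target = rng.uniform(300, 0.5 * qc_lo) if j % 2 == 0 else rng.uniform(1.2 * qc_hi, 1.8 * qc_hi)
            M[:, c] *= target / total
            qc_outlier[c] = True

        # condition-specific ambient soup: library-weighted average profile
        totals = M.sum(axis=0)
        soup = M.sum(axis=1)
        soup = soup / soup.sum() if soup.sum() > 0 else soup
        M_mixed = (1 - rho) * M + rho * totals * soup[:, None]
        counts = _nb_counts(M_mixed, config.nb_dispersion, rng)

        for c, ctype in enumerate(cell_types):
            columns.append(counts[:, c])
            meta_rows.append(dict(cell_type=ctype, condition=cond, is_doublet=False,
                                  source_types="", qc_outlier=bool(qc_outlier[c])))

        # doublets: one extra GSC-program cell + one cyst-program cell, summed
        n_dbl = int(round(delta / (1 - delta) * n_singlets)) if delta > 0 else 0
        if n_dbl:
            lib_a = rng.lognormal(config.library_mu, config.library_sigma, size=n_dbl)
            lib_b = rng.lognormal(config.library_mu, config.library_sigma, size=n_dbl)
            Ma = means[("GSC", cond)][:, None] * lib_a
            Mb = means[("cyst", cond)][:, None] * lib_b
            Ma = (1 - rho) * Ma + rho * Ma.sum(axis=0) * soup[:, None]
            Mb = (1 - rho) * Mb + rho * Mb.sum(axis=0) * soup[:, None]
            dbl = _nb_counts(Ma, config.nb_dispersion, rng) + _nb_counts(Mb, config.nb_dispersion, rng)
            for c in range(n_dbl):
                columns.append(dbl[:, c])
                meta_rows.append(dict(cell_type="doublet", condition=cond, is_doublet=True,
                                      source_types="GSC+cyst", qc_outlier=False))

    n_cells = len(columns)
    order = rng.permutation(n_cells)
    barcodes = [f"BC{i + 1:06d}" for i in range(n_cells)]
    count_matrix = sp.csr_matrix(np.stack(columns, axis=1)[:, order].astype(np.int64))
    cells = pd.DataFrame([meta_rows[i] for i in order], index=pd.Index(barcodes, name="barcode"))

    matrix = GeneExpressionMatrix(
        gene_ids=genes,
        cell_barcodes=barcodes,
        counts=count_matrix,
        cell_meta=cells[["condition"]].copy(),
    )
    planted = pd.DataFrame(
        [dict(gene=e.gene, cell_types="+".join(e.cell_types), log2fc=e.log2fc, category=e.category)
         for e in config.planted_effects]
    )
    if planted.empty:
        planted = pd.DataFrame(columns=["gene", "cell_types", "log2fc", "category"])
    soup_profiles = {}
    for cond in CONDITIONS:
        vec = np.zeros(len(genes))
        total = 0.0
        for ctype in CELL_TYPES:
            n = int(config.n_cells_per_type_per_condition.get(ctype, 0))
            vec += means[(ctype, cond)] * n
            total += means[(ctype, cond)].sum() * n
        soup_profiles[cond] = vec / total if total > 0 else vec
    ambient = pd.DataFrame(soup_profiles, index=pd.Index(genes, name="gene"))
    truth = SyntheticTruth(cells=cells, planted=planted, ambient_profile=ambient)
    return matrix, truth


# ---------------------------------------------------------------------------
# assay simulators


def simulate_ddpcr(true_lambda_per_target: dict, n_droplets: int, n_replicates: int = 1,
                   seed: int = None, sample_id: str = "sample") -> list:
    """Simulate ddPCR wells: positives ~ Binomial(n_droplets, 1 - exp(-lambda)).

    ``true_lambda_per_target`` maps target name to mean copies per droplet.
    """
    if n_droplets < 1:
        raise ValidationError("n_droplets must be >= 1")
    rng = np.random.default_rng(seed)
    wells = []
    for target, lam in true_lambda_per_target.items():
        if lam < 0:
            raise ValidationError(f"lambda for {target!r} must be >= 0")
        p = 1.0 - math.exp(-lam)
        positives = rng.binomial(n_droplets, p, size=n_replicates)
        for k in positives:
            wells.append(DdpcrWell(sample_id=sample_id, target=target,
                                   droplets_total=n_droplets, droplets_positive=int(k)))
    return wells


@dataclass(frozen=True)
class CrossCounts:
    """Offspring counts from one magnification cross.

    ``n_excluded`` are Bar-marked offspring that never enter scoring.
    """

    label: str
    n_wildtype: int
    n_bobbed: int
    n_excluded: int = 0

    @property
    def n_scored(self) -> int:
        return self.n_wildtype + self.n_bobbed


def simulate_cross(true_magnification_prob: float, n_scored: int,
                   excluded_fraction: float = 0.5, seed: int = None,
                   label: str = "cross") -> CrossCounts:
    """Simulate scoring of one cross: wild-type ~ Binomial(n_scored, p)."""
    if not 0 <= true_magnification_prob <= 1:
        raise ValidationError("magnification probability must be in [0, 1]")
    if n_scored <= 0:
        raise ValidationError("n_scored must be positive")
    if not 0 <= excluded_fraction < 1:
        raise ValidationError("excluded_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_wt = int(rng.binomial(n_scored, true_magnification_prob))
    # Bar-marked siblings arise independently and are never scored
    expected_excluded = n_scored * excluded_fraction / (1 - excluded_fraction)
    n_excl = int(rng.poisson(expected_excluded)) if expected_excluded > 0 else 0
    return CrossCounts(label=label, n_wildtype=n_wt, n_bobbed=n_scored - n_wt, n_excluded=n_excl)
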