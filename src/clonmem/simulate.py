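"""Synthetic single-cell multiome, lineage-barcode, footprint and spatial data.

Every downstream stage of the package (clone calling, deviation scoring, the
clonal-variance permutation test, co-binding statistics, spatial tumor
segmentation) can be exercised on the output of this module, which plants
known clonal structure, condition effects, a high-memory clone subpopulation,
barcode sequencing errors, co-occurring footprint families, and Axin2-high
tumors, and records the ground truth alongside.

The generative model for per-cell latent family scores is

    s[i, a] = clone_effect[clone(i), a] + shift[a] * exposed(i) + noise[i, a]

with ``Var(clone_effect) / (Var(clone_effect) + Var(noise)) = icc[a]`` and
unit total variance, so the intraclass correlation of each family is a direct
config parameter.  Counts are conditional-Poisson: each cell draws a total
depth from a lognormal and distributes it multinomially over features with
rates tilted by the cell's latent scores through the feature-family
annotation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

ANCHOR = "TAGACAT"
#: invariant dinucleotides of the 48-bp clonal barcode, at 0-based offsets
#: 4, 10, 16, 22, 28, 34, 40, 46 (one every 6 bases after a 4-base random block)
INVARIANT_DINUCLEOTIDES = ("CT", "AC", "TC", "GT", "TG", "CA", "AT", "GC")
INVARIANT_OFFSETS = tuple(4 + 6 * i for i in range(8))
BARCODE_LENGTH = 48
_BASES = np.array(list("ACGT"))

#: forward oligonucleotide of the barcode library: a 5' constant region ending
#: in the anchor-homologous AGAGACAT, the 48-bp variable region (8 x [NNNN +
#: invariant dinucleotide]) and a 3' constant tail carrying the reverse-oligo
#: annealing site.
FORWARD_OLIGO = ("CCTATAGTGAGTCGTATTAGAGACAT"
                 "NNNNCTNNNNACNNNNTCNNNNGTNNNNTGNNNNCANNNNATNNNNGC"
                 "ATCATCAAGATCGGAAGAGCGTCGTG")
_OLIGO_VARIABLE_START = FORWARD_OLIGO.index("AGAGACAT") + len("AGAGACAT")


def instantiate_forward_oligo(rng: np.random.Generator | None = None,
                              seed: int = 0) -> str:
    """Substitute random bases for the N positions of the forward oligo."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return "".join(b if b != "N" else str(rng.choice(_BASES))
                   for b in FORWARD_OLIGO)


def anchored_oligo_read(rng: np.random.Generator | None = None,
                        seed: int = 0) -> str:
    """A sequencing read instantiated from the forward oligo: the TAGACAT
    anchor followed by the oligo's variable region and 3' constant tail."""
    return ANCHOR + instantiate_forward_oligo(rng, seed)[_OLIGO_VARIABLE_START:]

# RNG stream offsets: one independent stream per output artifact so that
# regenerating e.g. the barcode reads does not perturb the count matrices.
_STREAMS = {
    "multiome": 1,
    "barcodes": 2,
    "reads": 3,
    "footprints": 4,
    "spatial": 5,
    "scores": 6,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the clonal organoid experiment: six organoid lines
    (three healthy controls, three derived during chronic colitis), ~30
    barcoded clones per line, and a colitis-exposed subpopulation of clones
    carrying an exceptionally strong AP-1-like memory.
    """

    seed: int = 0
    n_samples: int = 6
    conditions: tuple[str, ...] = ("control", "control", "control",
                                   "colitis", "colitis", "colitis")
    control_condition: str = "control"
    n_cells_per_sample: int = 500
    n_peaks: int = 2000
    n_genes: int = 1000
    n_families: int = 10
    n_clones_per_sample: int = 30
    clone_size_distribution: str = "uniform"  # or "geometric"
    clone_size_param: float = 0.1             # geometric success probability
    icc_per_family: tuple[float, ...] | float = 0.3
    condition_shift_per_family: tuple[float, ...] | float = 0.0
    ap1_families: tuple[int, ...] = (0,)
    high_memory_fraction: float = 0.0
    delta_high: float = 2.0
    depth_lognormal_params: tuple[float, float] = (np.log(2000.0), 0.5)
    rate_coupling: float = 0.25   # tilt of feature rates per unit latent score

    # barcode library
    barcode_error_rate: float = 0.01
    umis_per_cell: int = 80
    reads_per_umi: int = 5
    junk_fraction: float = 0.0
    min_barcode_distance: int = 9

    # footprints
    footprint_families: tuple[str, ...] = ("AP1", "FOX", "HNF4/PPAR", "ETS")
    footprint_conditions: tuple[str, ...] = ("control", "recovered")
    n_footprint_peaks: int = 2000
    peak_width: int = 500
    p_ap1_memory: float = 0.3
    footprint_cooccurrence: dict | float = 0.1
    footprint_base_rate: float = 0.1
    memory_delta_range: tuple[float, float] = (0.25, 0.5)
    cooccurrence_max_offset_bins: int = 1

    # spatial grid
    spatial_grid: tuple[int, int] = (80, 80)
    bin_size_um: float = 16.0
    n_tumors: int = 12
    tumor_radius_bins: int = 4
    axin2_fold_change: float = 8.0
    axin2_base_share: float = 0.04   # baseline fraction of reads from Axin2
    n_spatial_factors: int = 3       # smooth latent tissue programs
    spatial_structure_strength: float = 0.3
    tumor_expression_shift: float = 0.5   # breadth of the adenoma program
    n_high_ap1_tumors: int = 3
    program_fold_change: float = 4.0
    n_spatial_probes: int = 200
    n_program_probes: int = 20
    spatial_depth_lognormal: tuple[float, float] = (np.log(1500.0), 0.4)
    spatial_qc_fail_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_samples != len(self.conditions):
            raise ValueError("conditions must provide one label per sample")
        if self.n_cells_per_sample <= 0:
            raise ValueError("need at least one cell per sample")
        if self.n_clones_per_sample <= 0:
            raise ValueError("need at least one clone per sample")
        for p in (self.high_memory_fraction, self.junk_fraction,
                  self.p_ap1_memory, self.footprint_base_rate,
                  self.spatial_qc_fail_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.barcode_error_rate >= 0.5:
            raise ValueError("barcode_error_rate >= 0.5: clone recovery undefined")
        icc = np.broadcast_to(np.asarray(self.icc_per_family, float),
                              (self.n_families,))
        if np.any(icc < 0) or np.any(icc >= 1):
            raise ValueError("icc_per_family must lie in [0, 1)")
        if self.clone_size_distribution not in ("uniform", "geometric"):
            raise ValueError("clone_size_distribution must be uniform or geometric")

    # -- derived vectors -------------------------------------------------
    @property
    def icc(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.icc_per_family, float), (self.n_families,)).copy()

    @property
    def condition_shift(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.condition_shift_per_family, float),
            (self.n_families,)).copy()

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=lambda o: list(o)))


# ---------------------------------------------------------------------------
# latent clone-structured scores
# ---------------------------------------------------------------------------

def _clone_sizes(rng: np.random.Generator, n_clones: int, n_cells: int,
                 distribution: str, param: float) -> np.ndarray:
    if distribution == "uniform":
        sizes = np.full(n_clones, n_cells // n_clones)
        sizes[: n_cells - sizes.sum()] += 1
    else:  # geometric, renormalized to the requested cell count
        draws = rng.geometric(param, size=n_clones).astype(float)
        sizes = np.maximum(1, np.round(draws / draws.sum() * n_cells)).astype(int)
        while sizes.sum() > n_cells:
            sizes[np.argmax(sizes)] -= 1
        while sizes.sum() < n_cells:
            sizes[np.argmin(sizes)] += 1
    return sizes


def simulate_clone_scores(n_clones: int, cells_per_clone: int, n_features: int,
                          icc: float | np.ndarray, seed: int = 0,
                          clone_shift: np.ndarray | None = None):
    """Clone-structured score matrix with known intraclass correlation.

    Returns ``(scores, clone_labels)`` where ``scores`` is
    ``(n_clones * cells_per_clone, n_features)`` with unit total variance per
    feature and ``Var(clone effect) = icc``.  ``clone_shift`` (optional,
    ``(n_clones, n_features)``) is added to the clone effects, for planting
    condition- or memory-level structure on top of the heritable component.
    """
    rng = np.random.default_rng([_STREAMS["scores"], seed])
    icc = np.broadcast_to(np.asarray(icc, float), (n_features,))
    labels = np.repeat(np.arange(n_clones), cells_per_clone)
    clone_eff = rng.standard_normal((n_clones, n_features)) * np.sqrt(icc)
    if clone_shift is not None:
        clone_eff = clone_eff + clone_shift
    noise = rng.standard_normal((labels.size, n_features)) * np.sqrt(1.0 - icc)
    return clone_eff[labels] + noise, labels


# ---------------------------------------------------------------------------
# multiome
# ---------------------------------------------------------------------------

def simulate_multiome(config: SimulationConfig):
    """Generate cells, sparse peak/gene count matrices, annotations and truth.

    Returns ``(cells, peak_counts, gene_counts, annotation, truth)``:

    * ``cells`` — DataFrame (cell_id, sample, condition, barcode index)
    * ``peak_counts`` / ``gene_counts`` — CSR matrices, cells x features
    * ``annotation`` — dict with ``peak_families`` (peaks x families CSR, 0/1),
      ``gene_programs`` (programs x genes weights, rows sum to 1),
      ``peaks`` (BED-style DataFrame) and feature id lists
    * ``truth`` — dict with per-cell clone labels, latent scores, the exposed
      flag, clone tables and the high-memory clone set
    """
    rng = config.rng("multiome")
    n_fam = config.n_families
    icc = config.icc
    shift = config.condition_shift

    samples = [f"S{j}" for j in range(config.n_samples)]
    exposed_cond = {c for c in config.conditions if c != config.control_condition}

    cell_rows, clone_rows = [], []
    clone_effects = []
    clone_of_cell = []
    high_clones: list[int] = []
    clone_id = 0
    for j, sample in enumerate(samples):
        condition = config.conditions[j]
        sizes = _clone_sizes(rng, config.n_clones_per_sample,
                             config.n_cells_per_sample,
                             config.clone_size_distribution,
                             config.clone_size_param)
        exposed = condition in exposed_cond
        n_high = (rng.binomial(len(sizes), config.high_memory_fraction)
                  if exposed else 0)
        high_idx = set(rng.choice(len(sizes), size=n_high, replace=False)
                       .tolist()) if n_high else set()
        for k, size in enumerate(sizes):
            eff = rng.standard_normal(n_fam) * np.sqrt(icc)
            if exposed:
                eff = eff + shift
                if k in high_idx:
                    eff[list(config.ap1_families)] += config.delta_high
                    high_clones.append(clone_id)
            clone_effects.append(eff)
            clone_rows.append({"clone_id": clone_id, "sample": sample,
                               "condition": condition, "size": int(size),
                               "high_memory": clone_id in high_clones})
            clone_of_cell.extend([clone_id] * size)
            clone_id += 1
        for i in range(config.n_cells_per_sample):
            cell_rows.append({"cell_id": f"{sample}_C{i:05d}", "sample": sample,
                              "condition": condition})

    cells = pd.DataFrame(cell_rows)
    clone_of_cell = np.asarray(clone_of_cell)
    clone_effects = np.vstack(clone_effects)
    n_cells = len(cells)

    noise = rng.standard_normal((n_cells, n_fam)) * np.sqrt(1.0 - icc)
    latent = clone_effects[clone_of_cell] + noise

    # feature-family annotation: each family marks a disjoint block of peaks;
    # half of the peaks stay unannotated background.
    peak_families = np.zeros(config.n_peaks, dtype=int) - 1
    per_fam = config.n_peaks // (2 * n_fam)
    for a in range(n_fam):
        peak_families[a * per_fam:(a + 1) * per_fam] = a
    ann = sparse.csr_matrix(
        (np.ones((peak_families >= 0).sum()),
         (np.flatnonzero(peak_families >= 0),
          peak_families[peak_families >= 0])),
        shape=(config.n_peaks, n_fam))

    peak_counts = _counts_from_latent(rng, latent, ann, config.n_peaks,
                                      config.rate_coupling,
                                      config.depth_lognormal_params)

    # gene programs: one program per family, Dirichlet weights concentrated on
    # a disjoint block of genes (rows sum to 1, as an LDA topic-gene matrix).
    gene_programs = np.zeros((n_fam, config.n_genes))
    genes_per_prog = config.n_genes // (2 * n_fam)
    for a in range(n_fam):
        block = slice(a * genes_per_prog, (a + 1) * genes_per_prog)
        w = rng.dirichlet(np.full(genes_per_prog, 0.5))
        gene_programs[a, block] = 0.9 * w
        bg = rng.dirichlet(np.full(config.n_genes, 1.0))
        gene_programs[a] += 0.1 * bg
    gene_ann = sparse.csr_matrix(gene_programs.T)
    gene_counts = _counts_from_latent(rng, latent, gene_ann, config.n_genes,
                                      config.rate_coupling,
                                      (config.depth_lognormal_params[0] - 1.0,
                                       config.depth_lognormal_params[1]))

    peaks = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(config.n_peaks) * 1000,
        "end": np.arange(config.n_peaks) * 1000 + config.peak_width,
        "peak_id": [f"peak_{i}" for i in range(config.n_peaks)],
    })
    annotation = {
        "peak_families": ann,
        "gene_programs": gene_programs,
        "peaks": peaks,
        "peak_ids": peaks["peak_id"].tolist(),
        "gene_ids": [f"gene_{g}" for g in range(config.n_genes)],
        "family_ids": [f"family_{a}" for a in range(n_fam)],
    }
    truth = {
        "clone_of_cell": clone_of_cell,
        "latent_scores": latent,
        "clones": pd.DataFrame(clone_rows),
        "high_memory_clones": np.asarray(high_clones, dtype=int),
        "exposed": cells["condition"].isin(exposed_cond).to_numpy(),
    }
    return cells, peak_counts, gene_counts, annotation, truth


def _counts_from_latent(rng, latent, annotation, n_features, coupling,
                        depth_params) -> sparse.csr_matrix:
    """Multinomial counts per cell with rates tilted by latent family scores."""
    n_cells = latent.shape[0]
    base = rng.lognormal(0.0, 0.5, size=n_features)
    tilt = latent @ annotation.T.toarray() if sparse.issparse(annotation) \
        else latent @ annotation.T
    rates = base[None, :] * np.exp(coupling * tilt)
    rates /= rates.sum(axis=1, keepdims=True)
    depths = np.maximum(1, rng.lognormal(*depth_params, size=n_cells)
                        .round().astype(np.int64))
    rows, cols, vals = [], [], []
    for i in range(n_cells):
        c = rng.multinomial(depths[i], rates[i])
        nz = np.flatnonzero(c)
        rows.append(np.full(nz.size, i))
        cols.append(nz)
        vals.append(c[nz])
    return sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_cells, n_features), dtype=np.int64)


# ---------------------------------------------------------------------------
# barcode library
# ---------------------------------------------------------------------------

def barcode_template(rng: np.random.Generator) -> str:
    """One 48-mer: 8 blocks of 4 random bases + an invariant dinucleotide."""
    parts = []
    for dinuc in INVARIANT_DINUCLEOTIDES:
        parts.append("".join(rng.choice(_BASES, size=4)))
        parts.append(dinuc)
    return "".join(parts)


def sample_clone_barcodes(n: int, seed: int = 0, min_distance: int = 9,
                          rng: np.random.Generator | None = None) -> list[str]:
    """Draw consensus barcodes with pairwise Levenshtein distance >= min_distance.

    The separation guarantees that distance-4 consensus clustering cannot
    merge two planted clones.
    """
    import edlib

    if rng is None:
        rng = np.random.default_rng([_STREAMS["barcodes"], seed])
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        cand = barcode_template(rng)
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("cannot satisfy min_distance; lower it")
        if all(edlib.align(cand, b, task="distance")["editDistance"]
               >= min_distance for b in out):
            out.append(cand)
    return out


def _apply_errors(rng, barcodes: np.ndarray, rate: float) -> np.ndarray:
    """i.i.d. per-base substitutions on an (n, 48) array of base characters."""
    if rate <= 0:
        return barcodes
    mask = rng.random(barcodes.shape) < rate
    # substitute with one of the three other bases, uniformly
    shifts = rng.integers(1, 4, size=barcodes.shape)
    idx = np.searchsorted(_BASES, barcodes)
    barcodes = barcodes.copy()
    barcodes[mask] = _BASES[(idx[mask] + shifts[mask]) % 4]
    return barcodes


def simulate_barcode_reads(clone_truth, config: SimulationConfig,
                           consensus: dict[int, str] | None = None):
    """Emit barcode reads for every cell of ``clone_truth``.

    ``clone_truth`` is either the truth dict of :func:`simulate_multiome`
    together with its cells table, or a DataFrame with columns ``cell_id``
    and ``clone_id``.  Each cell emits ``umis_per_cell`` UMIs with
    ``reads_per_umi`` reads each; reads carry a 0-3 base stagger, the TAGACAT
    anchor, the clone's 48-mer with i.i.d. per-base substitution errors, and
    a constant 3' tail.  A ``junk_fraction`` of reads is replaced by junk
    (half broken-anchor reads, half all-G-UMI reads).

    Returns ``(reads, consensus)`` where ``reads`` has columns cell_barcode,
    umi, read_sequence.
    """
    if isinstance(clone_truth, dict):
        raise TypeError("pass a DataFrame with cell_id and clone_id columns")
    if len(clone_truth) == 0:
        raise ValueError("clone_truth is empty: no cells to emit reads for")
    rng = config.rng("reads")
    clone_ids = np.sort(clone_truth["clone_id"].unique())
    if consensus is None:
        seqs = sample_clone_barcodes(len(clone_ids), seed=config.seed,
                                     min_distance=config.min_barcode_distance)
        consensus = dict(zip(clone_ids.tolist(), seqs))

    n_cells = len(clone_truth)
    n_umis = config.umis_per_cell
    n_reads = config.reads_per_umi
    total = n_cells * n_umis * n_reads

    cell_idx = np.repeat(np.arange(n_cells), n_umis * n_reads)
    umi_idx = np.tile(np.repeat(np.arange(n_umis), n_reads), n_cells)

    umi_pool = rng.choice(_BASES, size=(n_cells * n_umis, 10))
    # regenerate the (vanishingly rare) all-G UMIs so real reads never carry one
    all_g = (umi_pool == "G").all(axis=1)
    umi_pool[all_g] = rng.choice(np.array(list("ACT")),
                                 size=(all_g.sum(), 10))
    umis = np.array(["".join(r) for r in umi_pool])

    bc_chars = np.array(
        [list(consensus[c]) for c in clone_truth["clone_id"].to_numpy()])
    read_bc = _apply_errors(rng, bc_chars[cell_idx], config.barcode_error_rate)
    tail = "ATCATCAAGATC"
    staggers = ["", "A", "GG", "TAC"]
    stagger_pick = rng.integers(0, 4, size=total)
    barcodes48 = ["".join(r) for r in read_bc]
    read_seqs = [staggers[stagger_pick[i]] + ANCHOR + barcodes48[i] + tail
                 for i in range(total)]

    cell_barcodes = clone_truth["cell_id"].to_numpy()[cell_idx]
    read_umis = umis[cell_idx * n_umis + umi_idx]

    reads = pd.DataFrame({"cell_barcode": cell_barcodes, "umi": read_umis,
                          "read_sequence": read_seqs})
    if config.junk_fraction > 0:
        junk = rng.random(total) < config.junk_fraction
        which = np.flatnonzero(junk)
        half = which[: which.size // 2]
        rest = which[which.size // 2:]
        # broken anchor: a fully random sequence of the same length
        for i in half:
            reads.iat[i, 2] = "".join(
                rng.choice(_BASES, size=len(reads.iat[i, 2])))
        reads.iloc[rest, 1] = "G" * 10
    return reads, consensus


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def simulate_footprints(config: SimulationConfig):
    """Per-condition 10-bp-binned footprint scores with planted co-occurrence.

    AP-1 memory sites (score gain drawn from ``memory_delta_range``) are
    planted in a ``p_ap1_memory`` fraction of peaks.  For each partner
    family, peaks with an AP-1 memory site receive a partner memory site with
    probability ``footprint_cooccurrence`` (per-family dict or scalar) and
    peaks without one with probability ``footprint_base_rate``; setting the
    co-occurrence equal to the base rate yields independence (odds ratio 1).

    Returns ``(sites, truth)``: a FootprintSiteTable DataFrame (site_id,
    peak_id, bin_start, family, score_<condition>...) and a truth dict.
    """
    rng = config.rng("footprints")
    ref = config.footprint_families[0]
    partners = config.footprint_families[1:]
    cond_ctrl, cond_case = config.footprint_conditions[:2]
    n_bins = config.peak_width // 10
    lo, hi = config.memory_delta_range

    if isinstance(config.footprint_cooccurrence, dict):
        cooc = {f: config.footprint_cooccurrence.get(f, config.footprint_base_rate)
                for f in partners}
    else:
        cooc = {f: float(config.footprint_cooccurrence) for f in partners}

    rows = []
    ap1_peaks = rng.random(config.n_footprint_peaks) < config.p_ap1_memory
    truth_rows = []
    sid = 0

    def add_site(peak, fam, bin_idx, memory):
        nonlocal sid
        ctrl = rng.uniform(0.2, 0.5)
        delta = rng.uniform(lo, hi) if memory else rng.uniform(-0.1, 0.1)
        case = float(np.clip(ctrl + delta, 0.0, 1.0))
        rows.append({"site_id": f"site_{sid}", "peak_id": f"peak_{peak}",
                     "bin_start": int(bin_idx) * 10, "family": fam,
                     f"score_{cond_ctrl}": round(ctrl, 6),
                     f"score_{cond_case}": round(case, 6)})
        truth_rows.append({"site_id": f"site_{sid}", "peak_id": f"peak_{peak}",
                           "family": fam, "memory": memory})
        sid += 1

    for p in range(config.n_footprint_peaks):
        ap1_bin = int(rng.integers(2, n_bins - 2))
        if ap1_peaks[p]:
            add_site(p, ref, ap1_bin, True)
        elif rng.random() < 0.3:           # non-memory reference site
            add_site(p, ref, ap1_bin, False)
        for fam in partners:
            prob = cooc[fam] if ap1_peaks[p] else config.footprint_base_rate
            if rng.random() < prob:
                off = int(rng.integers(-config.cooccurrence_max_offset_bins,
                                       config.cooccurrence_max_offset_bins + 1))
                b = int(np.clip(ap1_bin + off, 0, n_bins - 1))
                add_site(p, fam, b, True)
            elif rng.random() < 0.15:      # non-memory partner site elsewhere
                add_site(p, fam, int(rng.integers(0, n_bins)), False)

    sites = pd.DataFrame(rows)
    truth = {"sites": pd.DataFrame(truth_rows),
             "ap1_memory_peaks": np.flatnonzero(ap1_peaks)}
    return sites, truth


# ---------------------------------------------------------------------------
# spatial grid
# ---------------------------------------------------------------------------

def simulate_spatial(config: SimulationConfig):
    """Spatial expression grid with planted circular Axin2-high tumors.

    Returns ``(bins, counts, truth)``: a SpatialBinTable DataFrame (bin_id,
    x, y, total_reads), a bins x probes CSR count matrix, and a truth dict
    with per-bin tumor labels (-1 outside tumors), probe names and the set of
    high-AP-1 tumors (whose program probes are elevated
    ``program_fold_change``-fold).
    """
    rng = config.rng("spatial")
    nx, ny = config.spatial_grid
    r = config.tumor_radius_bins
    n_bins = nx * ny

    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xs, ys = xs.ravel(), ys.ravel()

    # place tumor centers with an edge gap of >= 6 bins between discs, so a
    # k=5 spatial NN graph over called bins cannot link two planted tumors
    # (the spatial analogue of the minimum barcode distance for clones)
    min_sep = 2 * r + 6
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < config.n_tumors:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("cannot place tumors without overlap; "
                               "reduce n_tumors or radius")
        cx = int(rng.integers(r + 1, nx - r - 1))
        cy = int(rng.integers(r + 1, ny - r - 1))
        if all((cx - ox) ** 2 + (cy - oy) ** 2 > min_sep ** 2
               for ox, oy in centers):
            centers.append((cx, cy))

    tumor_of_bin = np.full(n_bins, -1, dtype=int)
    for t, (cx, cy) in enumerate(centers):
        inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= r ** 2
        tumor_of_bin[inside] = t

    high = rng.choice(config.n_tumors, size=min(config.n_high_ap1_tumors,
                                                config.n_tumors),
                      replace=False) if config.n_tumors else np.array([], int)

    probes = ["Axin2"] + [f"prog_{g}" for g in range(config.n_program_probes)] \
        + [f"probe_{g}" for g in range(config.n_spatial_probes
                                       - 1 - config.n_program_probes)]
    base = rng.lognormal(0.0, 0.5, size=len(probes))
    # Axin2 is a WNT target with solid baseline expression in normal crypts;
    # a well-measured baseline keeps the adenoma fold change resolvable above
    # per-bin counting noise after smoothing.
    share = config.axin2_base_share
    base[0] = share / (1.0 - share) * base[1:].sum()

    # smooth latent tissue programs across the section: real sections carry
    # spatially coherent expression structure (cell-type composition), which
    # is what PC-space k-NN smoothing averages over.  Axin2 is left out of
    # the loadings so its baseline is spatially flat.
    fac = np.zeros((n_bins, config.n_spatial_factors))
    for l in range(config.n_spatial_factors):
        fx, fy = rng.uniform(0.5, 2.5, size=2)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        fac[:, l] = (np.sin(2 * np.pi * fx * xs / nx + phase[0])
                     + np.sin(2 * np.pi * fy * ys / ny + phase[1]))
    loadings = rng.normal(0.0, config.spatial_structure_strength,
                          size=(config.n_spatial_factors, len(probes)))
    loadings[:, 0] = 0.0
    rates = base[None, :] * np.exp(fac @ loadings)
    in_tumor = tumor_of_bin >= 0
    # adenomas rewire expression broadly (WNT activation), not only Axin2;
    # this global shift is what places tumor bins in their own region of
    # PC space, as in real sections
    tumor_loadings = rng.normal(0.0, config.tumor_expression_shift,
                                size=len(probes))
    tumor_loadings[0] = 0.0
    rates[in_tumor] *= np.exp(tumor_loadings)[None, :]
    rates[in_tumor, 0] *= config.axin2_fold_change
    in_high = np.isin(tumor_of_bin, high)
    rates[in_high, 1:1 + config.n_program_probes] *= config.program_fold_change
    rates /= rates.sum(axis=1, keepdims=True)

    depths = np.maximum(1, rng.lognormal(*config.spatial_depth_lognormal,
                                         size=n_bins).round().astype(np.int64))
    fail = rng.random(n_bins) < config.spatial_qc_fail_fraction
    depths[fail] = rng.integers(50, 300, size=fail.sum())

    rows, cols, vals = [], [], []
    for i in range(n_bins):
        c = rng.multinomial(depths[i], rates[i])
        nz = np.flatnonzero(c)
        rows.append(np.full(nz.size, i))
        cols.append(nz)
        vals.append(c[nz])
    counts = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_bins, len(probes)), dtype=np.int64)

    bins = pd.DataFrame({"bin_id": [f"bin_{i}" for i in range(n_bins)],
                         "x": xs, "y": ys,
                         "total_reads": np.asarray(counts.sum(axis=1)).ravel()})
    truth = {"tumor_of_bin": tumor_of_bin, "centers": centers,
             "high_ap1_tumors": np.sort(high),
             "probes": probes,
             "program_probes": probes[1:1 + config.n_program_probes]}
    return bins, counts, truth
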