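"""Read-level simulator for paired untreated/depleted droplet libraries.

The generative model mirrors how a single abundant contaminant transcript
distorts a droplet scRNA-seq experiment:

* Each of ``n_cells`` true cells draws a log-normal molecule count; a
  Beta-distributed fraction of its molecules (mean ``p_contaminant``) is
  the contaminant, the rest follow the cell type's expression program.
* Each of ``n_empty`` empty droplets draws a (smaller) log-normal molecule
  count from the ambient profile, a mixture of the contaminant (weight
  ``ambient_contaminant``) and the population-mean cell program.
* Sequencing reads are allocated to molecules multinomially with
  log-normal amplification weights whose spread grows as
  ``sigma0 * sqrt(PCR cycles)``; molecules drawing zero reads are lost —
  this is the dropout/saturation mechanism, which is why the simulator is
  read-level rather than UMI-level.
* Depletion removes each contaminant molecule independently with
  probability ``epsilon``; survivors pass a post-amplification bottleneck
  and are resequenced at the same total read budget, so both arms of a
  pair are comparable at matched depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import BenchConfig, ConfigError
from .containers import MoleculeTable

__all__ = [
    "ChemistryConstants", "TruthModel", "build_truth", "simulate_library",
    "apply_dash", "simulate_paired", "expected_fragment_length",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ChemistryConstants:
    """Fixed adapter overhead of the droplet 3' chemistry: a 82-base
    poly(dT) capture primer and a 30-base template-switching oligo flank
    every cDNA insert (112 bases total)."""

    polydt_primer_len: int = 82
    tso_primer_len: int = 30

    def __post_init__(self):
        if self.polydt_primer_len <= 0 or self.tso_primer_len <= 0:
            raise ValueError("primer lengths must be strictly positive")

    @property
    def adapter_overhead(self) -> int:
        return self.polydt_primer_len + self.tso_primer_len


def expected_fragment_length(insert_len: int,
                             chem: ChemistryConstants = ChemistryConstants()) -> int:
    """Expected library fragment length: insert plus the fixed adapter
    overhead (112 bases for the default chemistry)."""
    if insert_len < 0:
        raise ValueError("insert length must be non-negative")
    return int(insert_len) + chem.adapter_overhead


@dataclass
class TruthModel:
    """Ground truth of one simulated experiment.

    ``feature_ids[0]`` is the contaminant; ``feature_ids[1:]`` are the
    genes (``feature_ids[1]`` is the stem marker).  ``programs`` has one
    row per cell type, summing to 1 over the genes (the contaminant is
    excluded from every program).  ``ambient`` is a distribution over all
    features with ``ambient[0]`` equal to the configured contaminant
    weight.
    """

    feature_ids: np.ndarray          # (n_genes + 1,)
    programs: np.ndarray             # (K, n_genes), rows sum to 1
    type_props: np.ndarray           # (K,), sums to 1
    type_is_stem: np.ndarray         # (K,) bool
    ambient: np.ndarray              # (n_genes + 1,), sums to 1
    cell_barcodes: np.ndarray        # (n_cells,)
    cell_types: np.ndarray           # (n_cells,) int
    empty_barcodes: np.ndarray       # (n_empty,)
    config: BenchConfig

    @property
    def n_types(self) -> int:
        return self.programs.shape[0]

    def features_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.feature_ids, "name": self.feature_ids})


def _random_barcodes(n: int, rng: np.random.Generator, length: int = 16) -> np.ndarray:
    """n unique random 16-mer droplet barcodes."""
    out: list = []
    seen = set()
    while len(out) < n:
        block = rng.integers(0, 4, size=(n, length))
        for row in block:
            bc = "".join(_BASES[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
                if len(out) == n:
                    break
    return np.asarray(out, dtype=object)


def build_truth(config: BenchConfig,
                rng: Optional[np.random.Generator] = None) -> TruthModel:
    """Draw the ground truth (programs, ambient profile, type labels)
    deterministically from the scenario seed."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    K, G = config.n_types, config.n_genes
    ids = np.empty(G + 1, dtype=object)
    ids[0] = config.contaminant_name
    ids[1] = config.stem_marker_name
    ids[2:] = [f"gene-{i:04d}" for i in range(2, G + 1)]

    # shared baseline abundances; marker weight handled separately below
    baseline = rng.lognormal(0.0, config.program_sigma, size=G)
    baseline[0] = 0.0  # gene-space index 0 is the stem marker

    # disjoint type-specific marker gene sets (never the stem marker)
    marker_pool = rng.permutation(np.arange(1, G))[: K * config.markers_per_type]
    programs = np.tile(baseline, (K, 1))
    for t in range(K):
        sel = marker_pool[t * config.markers_per_type:(t + 1) * config.markers_per_type]
        programs[t, sel] *= config.marker_fold

    # stem flag: the last n_nonstem_types non-rare types are non-stem
    is_stem = np.ones(K, dtype=bool)
    if config.n_nonstem_types:
        is_stem[K - 1 - config.n_nonstem_types:K - 1] = False

    # stem marker takes a fixed share of the program in stem types only
    share = config.stem_marker_share
    for t in range(K):
        if is_stem[t]:
            rest = programs[t, 1:].sum()
            programs[t, 0] = share / (1.0 - share) * rest
        else:
            programs[t, 0] = 0.0
    programs /= programs.sum(axis=1, keepdims=True)

    # type proportions: last type rare, the rest uniform
    props = np.full(K, (1.0 - config.rare_type_prop) / max(K - 1, 1))
    props[-1] = config.rare_type_prop
    if K == 1:
        props[:] = 1.0

    # ambient: contaminant weight + population-mean cell program
    mean_program = props @ programs
    ambient = np.empty(G + 1)
    ambient[0] = config.ambient_contaminant
    ambient[1:] = (1.0 - config.ambient_contaminant) * mean_program

    cell_types = rng.choice(K, size=config.n_cells, p=props)
    barcodes = _random_barcodes(config.n_cells + config.n_empty, rng)
    return TruthModel(
        feature_ids=ids, programs=programs, type_props=props,
        type_is_stem=is_stem, ambient=ambient,
        cell_barcodes=barcodes[: config.n_cells], cell_types=cell_types,
        empty_barcodes=barcodes[config.n_cells:], config=config,
    )


def _lognormal_counts(median: float, sigma: float, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    counts = np.round(rng.lognormal(np.log(median), sigma, size=n)).astype(np.int64)
    return np.maximum(counts, 1)


def _allocate_reads(n_molecules: int, total_reads: int, sigma_amp: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Multinomial allocation of the read budget over molecules with
    log-normal amplification weights; returns per-molecule read counts."""
    if total_reads <= 0:
        raise ConfigError("total read budget must be positive")
    weights = rng.lognormal(0.0, sigma_amp, size=n_molecules)
    p = weights / weights.sum()
    return rng.multinomial(total_reads, p)


def simulate_library(truth: TruthModel, config: Optional[BenchConfig] = None,
                     rng: Optional[np.random.Generator] = None) -> MoleculeTable:
    """Simulate one untreated library as a read-level molecule table.

    Molecules receiving zero reads in the multinomial allocation are
    dropped; the retained table's reads sum exactly to ``total_reads``.
    """
    config = (config or truth.config).validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    G = config.n_genes
    n_cells, n_empty = config.n_cells, config.n_empty

    cell_mols = _lognormal_counts(config.cell_median_molecules,
                                  config.cell_sigma_log, n_cells, rng)
    empty_mols = _lognormal_counts(config.empty_median_molecules,
                                   config.empty_sigma_log, n_empty, rng)

    # per-cell contaminant fraction with realistic spread
    a = config.p_contaminant * config.p_concentration
    b = (1.0 - config.p_contaminant) * config.p_concentration
    if config.p_contaminant in (0.0, 1.0):
        p_cell = np.full(n_cells, config.p_contaminant)
    else:
        p_cell = rng.beta(a, b, size=n_cells)
    n_contam = rng.binomial(cell_mols, p_cell)

    barcode_codes = np.repeat(np.arange(n_cells + n_empty),
                              np.concatenate([cell_mols, empty_mols]))
    n_total = barcode_codes.size
    features = np.zeros(n_total, dtype=np.int32)  # feature 0 = contaminant

    # cell molecules: first n_contam[i] of each cell are contaminant, the
    # rest draw iid from the type program (== multinomial composition)
    cell_span = int(cell_mols.sum())
    offsets = np.concatenate([[0], np.cumsum(cell_mols)])
    contam_mask = np.zeros(cell_span, dtype=bool)
    within = np.arange(cell_span) - np.repeat(offsets[:-1], cell_mols)
    contam_mask = within < np.repeat(n_contam, cell_mols)

    mol_type = np.repeat(truth.cell_types, cell_mols)
    noncontam_idx = np.flatnonzero(~contam_mask)
    for t in range(truth.n_types):
        sel = noncontam_idx[mol_type[noncontam_idx] == t]
        if sel.size:
            # +1: gene-space index g maps to feature index g+1
            features[sel] = rng.choice(G, size=sel.size, p=truth.programs[t]) + 1

    # ambient molecules draw from the full ambient profile
    amb = slice(cell_span, n_total)
    features[amb] = rng.choice(G + 1, size=n_total - cell_span, p=truth.ambient)

    all_barcodes = np.concatenate([truth.cell_barcodes, truth.empty_barcodes])
    df = pd.DataFrame({
        "barcode": pd.Categorical.from_codes(barcode_codes,
                                             categories=all_barcodes.astype(str)),
        "feature": pd.Categorical.from_codes(features,
                                             categories=truth.feature_ids.astype(str)),
        "molecule": np.arange(n_total, dtype=np.int64),
        "reads": np.zeros(n_total, dtype=np.int64),
        "is_cell": barcode_codes < n_cells,
        "cell_type": np.where(barcode_codes < n_cells,
                              np.repeat(np.concatenate([truth.cell_types,
                                                        np.full(n_empty, -1)]),
                                        np.concatenate([cell_mols, empty_mols])),
                              -1),
    })

    sigma_amp = config.sigma0 * np.sqrt(config.pre_cycles)
    reads = _allocate_reads(n_total, config.total_reads, sigma_amp, rng)
    return MoleculeTable(df).with_reads(reads)


def apply_dash(molecules: MoleculeTable, epsilon: Optional[float] = None,
               post_cycles: Optional[int] = None,
               config: Optional[BenchConfig] = None,
               rng: Optional[np.random.Generator] = None) -> MoleculeTable:
    """In-silico depletion followed by post-amplification and resequencing.

    Each contaminant molecule is independently removed with probability
    ``epsilon``; non-contaminant molecules are never removed or relabelled.
    Survivors pass a bottleneck of size ``min(N, N/2**pre * 2**post)``
    (no bottleneck when ``post_cycles >= pre_cycles``), then fresh
    log-normal amplification weights with spread
    ``sigma0*sqrt(pre_cycles+post_cycles)`` reallocate the same total read
    budget.  The untreated arm of a pair is produced by this exact
    operation with ``epsilon=0`` so both arms are sequenced identically.
    """
    config = (config or BenchConfig()).validate()
    epsilon = config.epsilon if epsilon is None else epsilon
    post_cycles = config.post_cycles if post_cycles is None else post_cycles
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    if post_cycles < 0:
        raise ValueError("post_cycles must be >= 0")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    df = molecules.df
    contam = molecules.is_contaminant(config.contaminant_name)
    keep = np.ones(len(df), dtype=bool)
    if epsilon > 0 and contam.any():
        cut = rng.random(int(contam.sum())) < epsilon
        keep[np.flatnonzero(contam)[cut]] = False
    survivors = df.loc[keep]

    n_surv = len(survivors)
    if n_surv == 0:
        return MoleculeTable(survivors.reset_index(drop=True))

    bottleneck = min(n_surv, int(round(
        n_surv * 2.0 ** (post_cycles - config.pre_cycles))))
    if bottleneck < n_surv:
        pick = rng.choice(n_surv, size=bottleneck, replace=False)
        survivors = survivors.iloc[np.sort(pick)]

    sigma_amp = config.sigma0 * np.sqrt(config.pre_cycles + post_cycles)
    reads = _allocate_reads(len(survivors), config.total_reads, sigma_amp, rng)
    return MoleculeTable(survivors.reset_index(drop=True)).with_reads(reads)


def simulate_paired(config: BenchConfig) -> Tuple[TruthModel, MoleculeTable,
                                                  MoleculeTable, MoleculeTable]:
    """Full paired benchmark: one underlying library, sequenced untreated
    and after depletion at matched read depth.

    Returns ``(truth, base, untreated, dashed)`` where ``base`` is the
    first-pass library, ``untreated = apply_dash(base, epsilon=0)`` and
    ``dashed = apply_dash(base, epsilon=config.epsilon)``.
    """
    config.validate()
    ss = np.random.SeedSequence([config.seed, 99]).spawn(4)
    truth = build_truth(config, np.random.default_rng(ss[0]))
    base = simulate_library(truth, config, np.random.default_rng(ss[1]))
    untreated = apply_dash(base, epsilon=0.0, config=config,
                           rng=np.random.default_rng(ss[2]))
    dashed = apply_dash(base, epsilon=config.epsilon, config=config,
                        rng=np.random.default_rng(ss[3]))
    return truth, base, untreated, dashed
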