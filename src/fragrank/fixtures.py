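"""Deterministic synthetic data: toy molecules, random metabolite graphs,
and forward-simulated spectra.

The simulator runs the generative model forward: it walks the fragmentation
DAG top-down, samples each fragment's logRank from the conditional table
given its bond type and its parent's sampled logRank, gives every sampled
fragment a peak at its m/z with an intensity slot drawn uniformly inside its
logRank bin, and fills every remaining intensity rank with background peaks
placed away from all fragment masses.  Because the total peak count always
exceeds 64, fragment peaks keep exactly their sampled ranks and
``assign_log_ranks`` inverts the simulation (up to rare bin overflows, which
spill to the next free rank).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import MetaboliteEdge, MetaboliteGraph, MetaboliteNode, Molecule, parse_molecule
from .fraggraph import (
    BOND_TYPE_LABELS,
    BRIDGE_LABELS,
    DEFAULT_RULES,
    FragmentationGraph,
    build_fragmentation_graph,
)
from .model import N_PA, _BOND_INDEX
from .spectra import (
    MAX_LOG_RANK,
    MAX_RANK,
    Peak,
    Spectrum,
    assign_log_ranks,
    fragment_mz,
    log_rank_bin_range,
    write_mgf,
)

#: (id, SMILES) toy structures spanning all default bond types; includes the
#: worked examples (methane, ethanol, glycine, benzene).
TOY_SMILES: tuple[tuple[str, str], ...] = (
    ("methane", "C"),
    ("ethanol", "CCO"),
    ("glycine", "NCC(=O)O"),
    ("benzene", "c1ccccc1"),
    ("ethylamine", "CCN"),
    ("diethyl-ether", "CCOCC"),
    ("isobutanol", "CC(C)CO"),
    ("cyclohexane", "C1CCCCC1"),
    ("n-methylacetamide", "CNC(=O)C"),
    ("propanoic-acid", "CCC(=O)O"),
    ("ethanolamine", "NCCO"),
    ("toluene", "Cc1ccccc1"),
    ("alanine", "CC(N)C(=O)O"),
    # mid-size, natural-product-like structures: realistic dereplication
    # queries whose shuffled-mass decoys actually differ from the targets
    ("salicylic-acid", "OC(=O)c1ccccc1O"),
    ("vanillin", "COc1cc(C=O)ccc1O"),
    ("tyrosine", "NC(Cc1ccc(O)cc1)C(=O)O"),
    ("tryptophan", "NC(Cc1c[nH]c2ccccc12)C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
    ("pantothenate", "CC(C)(CO)C(O)C(=O)NCCC(=O)O"),
)


@dataclass
class SyntheticConfig:
    """Study conditions for simulated spectra and random graphs."""

    seed: int = 0
    n_molecules: int = 12
    n_nodes_range: tuple[int, int] = (4, 7)
    extra_edges_range: tuple[int, int] = (0, 2)
    bond_freqs: dict = field(
        default_factory=lambda: {"CC": 0.5, "NC": 0.25, "OC": 0.25}
    )
    node_mass_range: tuple[float, float] = (40.0, 160.0)
    n_peaks_range: tuple[int, int] = (70, 110)
    intensity_base: float = 1000.0
    intensity_decay: float = 0.94
    min_fragment_separation: float = 0.05
    max_fragments_per_graph: int = 40

    def __post_init__(self):
        total = sum(self.bond_freqs.values())
        if abs(total - 1.0) > 1e-9:
            self.bond_freqs = {
                k: v / total for k, v in self.bond_freqs.items()
            }
        if self.n_peaks_range[0] <= MAX_RANK:
            raise ValueError("n_peaks_range must start above 64 ranks")


def make_toy_molecules(config: SyntheticConfig | None = None) -> list[Molecule]:
    """Small parseable structures covering all default bond types."""
    return [parse_molecule(smi, mid) for mid, smi in TOY_SMILES]


# ---------------------------------------------------------------------------
# Random labelled metabolite graphs


def random_metabolite_graph(
    rng: np.random.Generator,
    n_nodes: int,
    n_extra_edges: int = 0,
    bond_freqs: dict | None = None,
    node_mass_range: tuple[float, float] = (40.0, 160.0),
    allow_parallel: bool = False,
    molecule_id: str = "synthetic",
) -> MetaboliteGraph:
    """A random connected labelled (multi)graph with random node masses.

    Built as a random spanning tree plus ``n_extra_edges`` chords; edge
    labels are drawn from ``bond_freqs`` and heteroatom sides of NC/OC edges
    are chosen at random.
    """
    freqs = bond_freqs or {"CC": 0.5, "NC": 0.25, "OC": 0.25}
    labels = sorted(freqs)
    probs = np.array([freqs[l] for l in labels])
    probs = probs / probs.sum()

    def draw_edge(u: int, v: int) -> MetaboliteEdge:
        label = labels[int(rng.choice(len(labels), p=probs))]
        hetero = None
        if label in ("NC", "OC", "SC", "OP", "PC"):
            hetero = int(u if rng.random() < 0.5 else v)
        return MetaboliteEdge(u=int(u), v=int(v), bond_type=label, hetero=hetero)

    edges: list[MetaboliteEdge] = []
    for v in range(1, n_nodes):
        edges.append(draw_edge(int(rng.integers(0, v)), v))
    present = {(min(e.u, e.v), max(e.u, e.v)) for e in edges}
    attempts = 0
    added = 0
    while added < n_extra_edges and attempts < 50 * (n_extra_edges + 1):
        attempts += 1
        u, v = rng.integers(0, n_nodes, size=2)
        if u == v:
            continue
        key = (min(int(u), int(v)), max(int(u), int(v)))
        if not allow_parallel and key in present:
            continue
        present.add(key)
        edges.append(draw_edge(int(u), int(v)))
        added += 1
    nodes = tuple(
        MetaboliteNode(
            atoms=frozenset({i}),
            mass=float(rng.uniform(*node_mass_range)),
        )
        for i in range(n_nodes)
    )
    return MetaboliteGraph(
        molecule_id=molecule_id, nodes=nodes, edges=tuple(edges)
    )


def _mass_separated(fg: FragmentationGraph, min_sep: float) -> bool:
    masses = sorted(f.mass for f in fg.fragments)
    return all(b - a >= min_sep for a, b in zip(masses, masses[1:]))


def make_recovery_graphs(
    config: SyntheticConfig, n_graphs: int | None = None
) -> list[FragmentationGraph]:
    """Random fragmentation graphs whose fragment masses are pairwise
    separated well beyond the match tolerance, so simulated annotation is
    unambiguous."""
    rng = np.random.default_rng(config.seed)
    out: list[FragmentationGraph] = []
    want = n_graphs or config.n_molecules
    k = 0
    while len(out) < want:
        k += 1
        n_nodes = int(rng.integers(*config.n_nodes_range, endpoint=True))
        n_extra = int(rng.integers(*config.extra_edges_range, endpoint=True))
        g = random_metabolite_graph(
            rng,
            n_nodes,
            n_extra,
            config.bond_freqs,
            config.node_mass_range,
            molecule_id=f"sim-{len(out)}",
        )
        fg = build_fragmentation_graph(g)
        if len(fg) < 4 or len(fg) > config.max_fragments_per_graph:
            continue
        if _mass_separated(fg, config.min_fragment_separation):
            out.append(fg)
        if k > 1000 * want:
            raise RuntimeError("could not draw enough separated graphs")
    return out


# ---------------------------------------------------------------------------
# Generating tables


def default_tables() -> tuple[np.ndarray, np.ndarray]:
    """A realistic generating model: conditional logRank tables and a
    background row.

    Bridges fragment more readily than 2-cuts, heteroatom bonds (NC/OC) more
    readily than CC, and a fragment whose parent was intense (low logRank)
    is more likely to appear itself.  Mass inside the observed bins rises
    toward the wide high bins, as intensity ranks do in real spectra.
    """
    propensity = {
        "NC": 0.60,
        "OC": 0.55,
        "CC": 0.45,
        "CC_CC": 0.25,
        "CC_NC": 0.30,
        "CC_OC": 0.32,
        "NC_NC": 0.36,
        "NC_OC": 0.38,
        "OC_OC": 0.34,
    }
    tilt = {
        "NC": 0.85,
        "OC": 0.88,
        "CC": 1.00,
        "CC_CC": 1.10,
        "CC_NC": 1.05,
        "CC_OC": 1.05,
        "NC_NC": 1.00,
        "NC_OC": 1.00,
        "OC_OC": 1.02,
    }
    pa_damp = np.array([1.0, 1.0, 0.95, 0.90, 0.85, 0.80, 0.75, 0.65])
    base = np.array([0.02, 0.05, 0.12, 0.20, 0.28, 0.33])

    cond = np.zeros((len(BOND_TYPE_LABELS), N_PA, MAX_LOG_RANK + 1))
    for b, label in enumerate(BOND_TYPE_LABELS):
        w = base * np.power(tilt[label], np.arange(MAX_LOG_RANK))
        w = w / w.sum()
        for p in range(N_PA):
            p_obs = propensity[label] * pa_damp[p]
            cond[b, p, :MAX_LOG_RANK] = p_obs * w
            cond[b, p, MAX_LOG_RANK] = 1.0 - p_obs
    null = np.array([0.01, 0.03, 0.07, 0.14, 0.25, 0.40, 0.10])
    null = null / null.sum()
    return cond, null


# ---------------------------------------------------------------------------
# Forward simulation


def simulate_spectrum(
    fg: FragmentationGraph,
    cond: np.ndarray,
    null: np.ndarray,
    config: SyntheticConfig,
    seed: int,
    spectrum_id: str | None = None,
) -> Spectrum:
    """Run the generative model forward for one fragmentation graph.

    Each non-root fragment samples a logRank from ``cond`` given its bond
    type and the smallest sampled logRank among its parents (root = 0); a
    sampled fragment receives a peak at its m/z on a uniformly-drawn free
    rank slot inside its bin (overflow spills to the next free rank).
    Background peaks fill every remaining rank slot at m/z kept away from
    all fragment masses; intensities follow a strictly decreasing
    exponential ladder, so re-ranking the peaks recovers the sampled bins
    exactly.  ``null`` documents the intended background shape; the realized
    background is whatever rank slots the fragments leave free.
    """
    rng = np.random.default_rng(seed)
    n = len(fg.fragments)
    sampled = [0] * n
    for i in range(1, n):
        frag = fg.fragments[i]
        pa = min((sampled[p] for p in frag.parents), default=0)
        b = _BOND_INDEX[frag.bond_type]
        sampled[i] = int(rng.choice(MAX_LOG_RANK + 1, p=cond[b, pa])) + 1

    n_peaks = int(rng.integers(*config.n_peaks_range, endpoint=True))
    emitters = [i for i in range(1, n) if sampled[i] <= MAX_LOG_RANK]
    occupied: dict[int, int] = {}
    for i in rng.permutation(emitters):
        lo, hi = log_rank_bin_range(sampled[int(i)])
        free = [r for r in range(lo, hi + 1) if r not in occupied]
        if free:
            r = int(free[int(rng.integers(len(free)))])
        else:  # bin overflow: spill to the next free rank slot
            r = hi + 1
            while r in occupied:
                r += 1
        if r <= n_peaks:
            occupied[r] = int(i)

    frag_mzs = [fragment_mz(f.mass, 1) for f in fg.fragments]
    guard = config.min_fragment_separation
    mz_lo, mz_hi = 50.0, max(200.0, frag_mzs[0])

    def noise_mz() -> float:
        while True:
            mz = float(rng.uniform(mz_lo, mz_hi))
            if all(abs(mz - fm) > guard for fm in frag_mzs):
                return mz

    peaks = []
    for r in range(1, n_peaks + 1):
        intensity = config.intensity_base * config.intensity_decay ** (r - 1)
        if r in occupied:
            mz = frag_mzs[occupied[r]]
        else:
            mz = noise_mz()
        peaks.append(Peak(mz=mz, intensity=intensity))
    peaks.sort(key=lambda p: p.mz)

    spec = Spectrum(
        id=spectrum_id or f"{fg.molecule_id}-sim-{seed}",
        precursor_mz=fragment_mz(fg.root.mass, 1),
        charge=1,
        adduct="[M+H]+",
        peaks=tuple(peaks),
    )
    return assign_log_ranks(spec)


def simulate_training_set(
    graphs: list[FragmentationGraph],
    cond: np.ndarray,
    null: np.ndarray,
    config: SyntheticConfig,
    seed: int,
    n_spectra: int,
) -> list[tuple[FragmentationGraph, Spectrum]]:
    """Cycle over the graphs emitting ``n_spectra`` simulated pairs."""
    pairs = []
    for k in range(n_spectra):
        fg = graphs[k % len(graphs)]
        pairs.append(
            (
                fg,
                simulate_spectrum(
                    fg, cond, null, config, seed=seed + k,
                    spectrum_id=f"{fg.molecule_id}-train-{k}",
                ),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Fixture corpus on disk


def write_fixture_corpus(
    outdir, seed: int = 0, n_spectra_per_molecule: int = 2
) -> dict[str, str]:
    """Write a self-contained toy corpus: SMILES TSV, simulated MGF, and a
    spectrum-molecule pairing TSV.  Returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = SyntheticConfig(seed=seed)
    cond, null = default_tables()
    molecules = make_toy_molecules()

    smiles_path = outdir / "molecules.tsv"
    with open(smiles_path, "w") as fh:
        fh.write("id\tsmiles\n")
        for mid, smi in TOY_SMILES:
            fh.write(f"{mid}\t{smi}\n")

    from .chem import build_metabolite_graph

    spectra = []
    pairing = []
    for mol in molecules:
        fg = build_fragmentation_graph(build_metabolite_graph(mol))
        if len(fg) < 4:
            continue
        for k in range(n_spectra_per_molecule):
            sid = f"sim-{mol.id}-{k}"
            spectra.append(
                simulate_spectrum(
                    fg, cond, null, config,
                    seed=(seed * 100003 + zlib.crc32(mol.id.encode()) % 1000 + k)
                    % (2**31),
                    spectrum_id=sid,
                )
            )
            pairing.append((sid, mol.id))

    mgf_path = outdir / "spectra.mgf"
    write_mgf(spectra, mgf_path)
    pairing_path = outdir / "pairs.tsv"
    with open(pairing_path, "w") as fh:
        fh.write("spectrum_id\tmolecule_id\n")
        for sid, mid in pairing:
            fh.write(f"{sid}\t{mid}\n")
    return {
        "molecules": str(smiles_path),
        "spectra": str(mgf_path),
        "pairs": str(pairing_path),
    }
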