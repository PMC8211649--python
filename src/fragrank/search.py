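"""Database search: candidate filtering, scoring, and target-decoy FDR.

Each query spectrum is matched against every database molecule whose neutral
mass (under some allowed adduct) lies within the precursor tolerance.  Every
candidate is scored against its real fragmentation graph (target) and a
mass-shuffled copy (decoy, one per molecule, seeded from the molecule id).
At a score cutoff t the false-discovery rate is estimated as
N_decoy(>=t) / N_target(>=t).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .chem import Molecule, PROTON_MASS, build_metabolite_graph
from .fraggraph import (
    DEFAULT_RULES,
    FragmentGraphTooLarge,
    FragmentationGraph,
    build_fragmentation_graph,
    make_decoy,
)
from .model import ScoringModel, annotate, score
from .spectra import Spectrum

#: Default precursor mass window in Da.
PRECURSOR_TOLERANCE = 0.02

#: adduct label -> (mass offset in Da, charge); neutral mass = mz*z - offset.
ADDUCTS: dict[str, tuple[float, int]] = {
    "[M+H]+": (PROTON_MASS, 1),
    "[M+Na]+": (22.989218, 1),
    "[M+K]+": (38.963158, 1),
    "[M+NH4]+": (18.033823, 1),
    "[M+2H]2+": (2 * PROTON_MASS, 2),
    "[M-H]-": (-PROTON_MASS, 1),
}


class UnknownAdductError(ValueError):
    def __init__(self, adduct: str):
        super().__init__(
            f"unknown adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        )


def observed_neutral_mass(s: Spectrum, adduct: str) -> float:
    """Neutral monoisotopic mass implied by the precursor m/z and adduct."""
    if adduct not in ADDUCTS:
        raise UnknownAdductError(adduct)
    offset, charge = ADDUCTS[adduct]
    return s.precursor_mz * charge - offset


@dataclass
class MatchResult:
    spectrum_id: str
    scan: int
    molecule_id: str
    molecule_mass: float
    adduct: str
    charge: int
    score: float
    is_decoy: bool
    rank: int = 0
    fdr: float | None = None


def filter_candidates(
    s: Spectrum,
    db: Sequence[Molecule],
    adducts: Sequence[str] = ("[M+H]+",),
    precursor_tolerance: float = PRECURSOR_TOLERANCE,
) -> list[tuple[Molecule, str]]:
    """Molecules whose mass matches the precursor under some adduct.

    The database is searched through a sorted mass index, so the lookup is
    logarithmic per adduct.
    """
    for a in adducts:
        if a not in ADDUCTS:
            raise UnknownAdductError(a)
    if not db:
        return []
    masses = np.array([m.monoisotopic_mass for m in db])
    order = np.argsort(masses, kind="stable")
    sorted_masses = masses[order]
    out: list[tuple[Molecule, str]] = []
    for adduct in adducts:
        target = observed_neutral_mass(s, adduct)
        lo = np.searchsorted(sorted_masses, target - precursor_tolerance, "left")
        hi = np.searchsorted(sorted_masses, target + precursor_tolerance, "right")
        for j in range(lo, hi):
            out.append((db[int(order[j])], adduct))
    return out


def _stable_seed(*parts) -> int:
    digest = hashlib.sha1("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def decoy_seed(global_seed: int, molecule_id: str) -> int:
    return _stable_seed("decoy", global_seed, molecule_id)


def run_search(
    spectra: Sequence[Spectrum],
    db: Sequence[Molecule],
    model: ScoringModel,
    seed: int,
    adducts: Sequence[str] = ("[M+H]+",),
    precursor_tolerance: float = PRECURSOR_TOLERANCE,
    rules: dict = DEFAULT_RULES,
    max_bridges: int = 2,
    max_two_cuts: int = 1,
    cache: dict[str, FragmentationGraph] | None = None,
    score_floor: float | None = None,
    best_hit_only: bool = False,
    skipped: list[str] | None = None,
) -> list[MatchResult]:
    """Score every spectrum against its candidate molecules and decoys.

    Per (spectrum, molecule) pair only the best-scoring adduct is kept; each
    molecule contributes one paired decoy (seeded from the molecule id, so
    the decoy is identical across spectra and runs).  Molecules whose
    fragmentation graph exceeds the size cap are recorded in ``skipped`` and
    ignored.  Output rows are canonically sorted by (spectrum, descending
    score), targets ranked per spectrum; FDR is assigned over all rows (or
    best-hit-per-spectrum rows when ``best_hit_only``).
    """
    fg_cache: dict[str, FragmentationGraph] = dict(cache or {})
    decoy_cache: dict[str, FragmentationGraph] = {}
    results: list[MatchResult] = []
    for scan, s in enumerate(spectra):
        per_pair: dict[tuple[str, bool], MatchResult] = {}
        for mol, adduct in filter_candidates(
            s, db, adducts, precursor_tolerance
        ):
            if mol.id not in fg_cache:
                try:
                    g = build_metabolite_graph(mol)
                    fg_cache[mol.id] = build_fragmentation_graph(
                        g, max_bridges, max_two_cuts, rules
                    )
                except FragmentGraphTooLarge:
                    if skipped is not None:
                        skipped.append(mol.id)
                    fg_cache[mol.id] = None  # type: ignore[assignment]
            fg = fg_cache[mol.id]
            if fg is None:
                continue
            if mol.id not in decoy_cache:
                decoy_cache[mol.id] = make_decoy(
                    fg, decoy_seed(seed, mol.id)
                )
            charge = ADDUCTS[adduct][1]
            query = replace(s, charge=charge)
            for fg_used, is_decoy in ((fg, False), (decoy_cache[mol.id], True)):
                sc = score(
                    fg_used,
                    query,
                    model,
                    seed=_stable_seed(seed, s.id, mol.id, is_decoy),
                )
                key = (mol.id, is_decoy)
                prev = per_pair.get(key)
                if prev is None or sc > prev.score:
                    per_pair[key] = MatchResult(
                        spectrum_id=s.id,
                        scan=scan,
                        molecule_id=mol.id,
                        molecule_mass=mol.monoisotopic_mass,
                        adduct=adduct,
                        charge=charge,
                        score=sc,
                        is_decoy=is_decoy,
                    )
        rows = sorted(
            per_pair.values(),
            key=lambda r: (-r.score, r.molecule_id, r.is_decoy),
        )
        rank = 0
        for r in rows:
            if not r.is_decoy:
                rank += 1
                r.rank = rank
        if score_floor is not None:
            kept = [
                r
                for r in rows
                if r.score >= score_floor or (not r.is_decoy and r.rank == 1)
            ]
        else:
            kept = rows
        results.extend(kept)
    results = compute_fdr(results, best_hit_only=best_hit_only)
    results.sort(key=lambda r: (r.spectrum_id, -r.score, r.molecule_id, r.is_decoy))
    return results


def compute_fdr(
    results: list[MatchResult], best_hit_only: bool = False
) -> list[MatchResult]:
    """Assign FDR = N_decoy(>=t) / N_target(>=t) at each row's own score.

    With ``best_hit_only`` the counts run over the best target and best
    decoy per spectrum only (the FDR of other rows is computed against that
    reduced score list).  Raises when no decoy rows are present.
    """
    if not results:
        return results
    if not any(r.is_decoy for r in results):
        raise ValueError("no decoy results: decoys are required for FDR")
    pool = results
    if best_hit_only:
        best: dict[tuple[str, bool], MatchResult] = {}
        for r in results:
            key = (r.spectrum_id, r.is_decoy)
            if key not in best or r.score > best[key].score:
                best[key] = r
        pool = list(best.values())
    target_scores = np.sort(
        np.array([r.score for r in pool if not r.is_decoy])
    )
    decoy_scores = np.sort(np.array([r.score for r in pool if r.is_decoy]))
    for r in results:
        n_target = len(target_scores) - np.searchsorted(
            target_scores, r.score, side="left"
        )
        n_decoy = len(decoy_scores) - np.searchsorted(
            decoy_scores, r.score, side="left"
        )
        r.fdr = float(n_decoy / n_target) if n_target > 0 else 0.0
    return results


# ---------------------------------------------------------------------------
# Reporting

_TSV_COLUMNS = (
    "spectrum_id",
    "scan",
    "molecule_id",
    "molecule_mass",
    "adduct",
    "charge",
    "score",
    "rank",
    "is_decoy",
    "fdr",
)


def write_results_tsv(results: Sequence[MatchResult], path) -> None:
    """Canonical TSV report, sorted by (spectrum_id, descending score)."""
    rows = sorted(
        results, key=lambda r: (r.spectrum_id, -r.score, r.molecule_id, r.is_decoy)
    )
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.spectrum_id}\t{r.scan}\t{r.molecule_id}\t"
                f"{r.molecule_mass:.6f}\t{r.adduct}\t{r.charge}\t"
                f"{r.score:.6f}\t{r.rank}\t{int(r.is_decoy)}\t"
                f"{r.fdr if r.fdr is None else format(r.fdr, '.6f')}\n"
            )


def summarize(results: Sequence[MatchResult]) -> dict:
    """Target match counts at FDR levels 0, 1% and 5%."""
    targets = [r for r in results if not r.is_decoy]
    out = {"n_targets": len(targets), "n_decoys": len(results) - len(targets)}
    for level in (0.0, 0.01, 0.05):
        out[f"matches_at_fdr_{level:g}"] = sum(
            1 for r in targets if r.fdr is not None and r.fdr <= level
        )
    return out


def write_summary_json(results: Sequence[MatchResult], path) -> None:
    with open(path, "w") as fh:
        json.dump(summarize(results), fh, indent=2)
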