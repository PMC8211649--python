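"""Tandem-mass-spectrum containers, MGF I/O, and logRank binning.

Peak abundance is summarized by intensity rank (rank 1 = most intense) and
then compressed into dyadic *logRank* bins: logRank = min(floor(log2 rank)
+ 1, 6), so ranks 1..64 occupy bins 1..6 (bin widths 1, 2, 4, 8, 16, 33).
Peaks ranked past 64 are treated as unmatchable background, and a molecular
fragment with no peak within tolerance is later annotated logRank 7.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .chem import PROTON_MASS

MAX_RANK = 64
MAX_LOG_RANK = 6
ABSENT_LOG_RANK = 7


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """One tandem mass spectrum.

    ``ranks``/``log_ranks`` are parallel to ``peaks`` once
    :func:`assign_log_ranks` has run; ``log_ranks`` holds None for peaks
    ranked past 64 (unmatchable).
    """

    id: str
    precursor_mz: float
    charge: int = 1
    adduct: str = "[M+H]+"
    peaks: tuple[Peak, ...] = ()
    ranks: tuple[int, ...] | None = None
    log_ranks: tuple[int | None, ...] | None = None

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class MgfBlockError:
    """A rejected MGF block: the file keeps parsing past it."""

    line: int
    message: str


def fragment_mz(neutral_mass: float, charge: int = 1) -> float:
    """m/z of a fragment ion: (neutral mass + z protons) / z."""
    return (neutral_mass + charge * PROTON_MASS) / charge


def log_rank_of(rank: int) -> int | None:
    """Dyadic logRank bin of an intensity rank; None past rank 64."""
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    if rank > MAX_RANK:
        return None
    return min(int(math.floor(math.log2(rank))) + 1, MAX_LOG_RANK)


def log_rank_bin_range(log_rank: int) -> tuple[int, int]:
    """Inclusive rank range of a logRank bin (bin 6 is widened to 32..64)."""
    if not 1 <= log_rank <= MAX_LOG_RANK:
        raise ValueError(f"logRank must be in 1..6, got {log_rank}")
    lo = 2 ** (log_rank - 1)
    hi = MAX_RANK if log_rank == MAX_LOG_RANK else 2**log_rank - 1
    return lo, hi


def assign_log_ranks(s: Spectrum) -> Spectrum:
    """Rank peaks by descending intensity and attach logRank bins.

    Ties in intensity are broken by ascending m/z, then by input order, so
    the assignment is deterministic and idempotent.  Raises ``ValueError``
    when the spectrum is empty or all intensities are zero.
    """
    if not s.peaks:
        raise ValueError(f"spectrum {s.id}: no peaks to rank")
    if all(p.intensity == 0 for p in s.peaks):
        raise ValueError(f"spectrum {s.id}: all intensities are zero")
    if any(p.intensity < 0 for p in s.peaks):
        raise ValueError(f"spectrum {s.id}: negative intensity")
    order = sorted(
        range(len(s.peaks)),
        key=lambda i: (-s.peaks[i].intensity, s.peaks[i].mz, i),
    )
    ranks = [0] * len(s.peaks)
    for pos, i in enumerate(order, start=1):
        ranks[i] = pos
    log_ranks = tuple(log_rank_of(r) for r in ranks)
    return replace(s, ranks=tuple(ranks), log_ranks=log_ranks)


# ---------------------------------------------------------------------------
# MGF reader / writer

_CHARGE_RE = re.compile(r"^(\d+)\s*([+-]?)")


def _parse_block(
    lines: list[tuple[int, str]], start_line: int
) -> Spectrum:
    title = None
    pepmass = None
    charge = 1
    adduct = "[M+H]+"
    peaks: list[Peak] = []
    for ln, line in lines:
        if "=" in line and not line[0].isdigit():
            key, _, value = line.partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "TITLE":
                title = value
            elif key == "PEPMASS":
                try:
                    pepmass = float(value.split()[0])
                except ValueError:
                    raise ValueError(f"line {ln}: bad PEPMASS {value!r}")
            elif key == "CHARGE":
                m = _CHARGE_RE.match(value)
                if not m:
                    raise ValueError(f"line {ln}: bad CHARGE {value!r}")
                charge = int(m.group(1))
            elif key in ("ADDUCT", "ION"):
                adduct = value
            # other headers ignored
        else:
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"line {ln}: bad peak line {line!r}")
            try:
                peaks.append(Peak(mz=float(parts[0]), intensity=float(parts[1])))
            except ValueError:
                raise ValueError(f"line {ln}: bad peak line {line!r}")
    if pepmass is None:
        raise ValueError(f"line {start_line}: block missing PEPMASS")
    if title is None:
        title = f"spectrum-at-line-{start_line}"
    spec = Spectrum(
        id=title,
        precursor_mz=pepmass,
        charge=charge,
        adduct=adduct,
        peaks=tuple(peaks),
    )
    return assign_log_ranks(spec) if peaks else spec


def read_mgf(path, errors: list[MgfBlockError] | None = None) -> list[Spectrum]:
    """Read an MGF file; malformed blocks are recorded (with a line number)
    in ``errors`` and skipped, the remaining blocks still parse.  Peak lists
    keep file order; intensity ranks are computed on load."""
    spectra: list[Spectrum] = []
    block: list[tuple[int, str]] | None = None
    block_start = 0
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                block = []
                block_start = ln
                continue
            if line == "END IONS":
                if block is None:
                    continue
                try:
                    spectra.append(_parse_block(block, block_start))
                except ValueError as exc:
                    if errors is not None:
                        errors.append(
                            MgfBlockError(line=block_start, message=str(exc))
                        )
                block = None
                continue
            if block is not None:
                block.append((ln, line))
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra as MGF with fixed %.6f numeric formatting."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            fh.write(f"ADDUCT={s.adduct}\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.6f} {p.intensity:.6f}\n")
            fh.write("END IONS\n")


def read_mzml(path) -> list[Spectrum]:
    """Optional mzML reader (pyteomics) behind the same Spectrum contract."""
    from pyteomics import mzml as _mzml

    spectra = []
    with _mzml.read(str(path)) as reader:
        for k, entry in enumerate(reader):
            if entry.get("ms level") != 2:
                continue
            try:
                precursor = entry["precursorList"]["precursor"][0][
                    "selectedIonList"
                ]["selectedIon"][0]
            except (KeyError, IndexError):
                continue
            mz = float(precursor["selected ion m/z"])
            charge = int(precursor.get("charge state", 1))
            peaks = tuple(
                Peak(mz=float(m), intensity=float(i))
                for m, i in zip(entry["m/z array"], entry["intensity array"])
            )
            spec = Spectrum(
                id=entry.get("id", f"scan-{k}"),
                precursor_mz=mz,
                charge=charge,
                peaks=peaks,
            )
            spectra.append(assign_log_ranks(spec) if peaks else spec)
    return spectra


def read_pairing_tsv(path) -> list[tuple[str, str]]:
    """Training pairing table: spectrum id <TAB> molecule id per line."""
    pairs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}: line {ln}: expected 'spectrum_id<TAB>molecule_id'"
                )
            if ln == 1 and parts[0].lower() in ("spectrum_id", "spectrum"):
                continue
            pairs.append((parts[0], parts[1]))
    return pairs
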