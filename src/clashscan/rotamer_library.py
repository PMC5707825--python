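"""Backbone-dependent rotamer library: loading, binning and queries.

The reader accepts a Dunbrack-style text format (columns: res_type, phi,
psi, frequency, chi1..chi4; "." for phi/psi marks a backbone-independent
row).  Queries return candidate rotamers in decreasing frequency order;
sites with undefined backbone torsions, or torsions falling in a bin the
file does not populate, fall back to the backbone-independent marginal,
so every query on a residue type with chi angles is answerable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

from ._aa import AA3_TO_AA1, CHI_COUNTS, STANDARD_AA1
from .errors import LibraryParseError, NoRotamersError

__all__ = ["Rotamer", "RotamerLibrary", "load_library", "load_default_library", "candidate_rotamers"]


@dataclass(frozen=True)
class Rotamer:
    res_type: str  # one-letter
    chi: tuple[float, ...]
    frequency: float

    def __post_init__(self) -> None:
        if len(self.chi) != CHI_COUNTS[self.res_type]:
            raise LibraryParseError(
                f"{self.res_type}: {len(self.chi)} chi values for a residue "
                f"with {CHI_COUNTS[self.res_type]} chi angles"
            )
        if self.frequency < 0:
            raise LibraryParseError("rotamer frequency must be nonnegative")


def _sort_rotamers(rotamers: list[Rotamer]) -> list[Rotamer]:
    # descending frequency; ties broken by ascending chi1 (then chi2, ...)
    return sorted(rotamers, key=lambda r: (-r.frequency, r.chi))


@dataclass
class RotamerLibrary:
    """Rotamers binned on (phi, psi) plus a backbone-independent marginal."""

    bin_width: float = 10.0
    entries: dict[tuple[str, int, int], list[Rotamer]] = field(default_factory=dict)
    marginal: dict[str, list[Rotamer]] = field(default_factory=dict)

    def bin_index(self, angle: float) -> int:
        """Half-open binning [lo, hi) of (-180, 180] onto [-180, 180)."""
        a = ((angle + 180.0) % 360.0) - 180.0
        return int(math.floor((a + 180.0) / self.bin_width))

    def sort_all(self) -> None:
        for key in self.entries:
            self.entries[key] = _sort_rotamers(self.entries[key])
        for key in self.marginal:
            self.marginal[key] = _sort_rotamers(self.marginal[key])

    def build_marginal(self) -> None:
        """Frequency-weighted aggregation of binned rows over all bins.

        Rows already present in the marginal (backbone-independent input
        rows) are kept as-is and take precedence for their residue type.
        """
        agg: dict[str, dict[tuple[float, ...], float]] = {}
        for (res_type, _pb, _sb), rotamers in self.entries.items():
            for r in rotamers:
                agg.setdefault(res_type, {})
                agg[res_type][r.chi] = agg[res_type].get(r.chi, 0.0) + r.frequency
        for res_type, chimap in agg.items():
            if res_type in self.marginal:
                continue
            total = sum(chimap.values())
            self.marginal[res_type] = _sort_rotamers(
                [
                    Rotamer(res_type, chi, f / total if total > 0 else 0.0)
                    for chi, f in chimap.items()
                ]
            )


def _parse_res_type(token: str, rowno: int) -> str:
    t = token.upper()
    if t in AA3_TO_AA1:
        return AA3_TO_AA1[t]
    if t in STANDARD_AA1:
        return t
    raise LibraryParseError(f"row {rowno}: unknown residue name {token!r}")


def load_library(source, bin_width: float = 10.0) -> RotamerLibrary:
    """Load a rotamer library from a path or file-like object.

    Row format: res_type phi psi frequency chi1 [chi2 chi3 chi4], with
    '#' comments and blank lines skipped.  Each row must carry exactly as
    many chi values as the residue type has chi angles.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lib = RotamerLibrary(bin_width=bin_width)
    for rowno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 4:
            raise LibraryParseError(f"row {rowno}: expected at least 4 columns")
        res_type = _parse_res_type(tokens[0], rowno)
        try:
            phi = None if tokens[1] == "." else float(tokens[1])
            psi = None if tokens[2] == "." else float(tokens[2])
            freq = float(tokens[3])
            chi = tuple(float(t) for t in tokens[4:])
        except ValueError as exc:
            raise LibraryParseError(f"row {rowno}: bad numeric field ({exc})") from exc
        try:
            rot = Rotamer(res_type, chi, freq)
        except LibraryParseError as exc:
            raise LibraryParseError(f"row {rowno}: {exc}") from exc
        if CHI_COUNTS[res_type] == 0:
            continue  # Ala/Gly rows are tolerated but carry no rotamers
        if phi is None or psi is None:
            lib.marginal.setdefault(res_type, []).append(rot)
        else:
            key = (res_type, lib.bin_index(phi), lib.bin_index(psi))
            lib.entries.setdefault(key, []).append(rot)
    lib.build_marginal()
    lib.sort_all()
    return lib


def load_default_library() -> RotamerLibrary:
    """The packaged minimal library (canonical chi modes, offline-safe)."""
    with resources.files("clashscan.data").joinpath("minimal_rotamers.txt").open() as fh:
        return load_library(fh)


def candidate_rotamers(
    lib: RotamerLibrary,
    res_type: str,
    phi: float | None,
    psi: float | None,
    min_frequency: float = 0.0,
) -> list[Rotamer]:
    """Rotamers to test at a site, most frequent first.

    Uses the (phi, psi) bin when both torsions are defined and the bin is
    populated; otherwise the backbone-independent marginal.  Rotamers
    below ``min_frequency`` are dropped (default keeps all).
    """
    if CHI_COUNTS.get(res_type, 0) == 0:
        raise NoRotamersError(f"{res_type} has no rotamers; use direct placement")
    rotamers: list[Rotamer] | None = None
    if phi is not None and psi is not None:
        rotamers = lib.entries.get((res_type, lib.bin_index(phi), lib.bin_index(psi)))
    if rotamers is None:
        rotamers = lib.marginal.get(res_type, [])
    return [r for r in rotamers if r.frequency >= min_frequency]
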