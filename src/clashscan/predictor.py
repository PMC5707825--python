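"""The decision cascade: fast-path assumptions, then rotamer testing.

A substitution is first screened by three assumptions that avoid any
geometry work: (a) glycine fits everywhere; (b) at an accessible site
(side-chain relative accessibility >= 0.5 whose original side chain has
at least 3 heavy atoms) every substitution fits; (c) a substitution to a
smaller side chain fits, unless the target is one of the short-but-
branched types (Val/Leu/Ile/Thr by default), which must still be tested.
Everything else is decided by exhaustively fitting backbone-dependent
rotamers in decreasing frequency order: the first rotamer with no
positive van der Waals overlap settles the verdict as "fits"; if none
fits, the substitution is predicted to cause a clash.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._aa import SIDECHAIN_SIZE, STANDARD_AA1
from .clash_engine import ClashParams, ClashResult, neighborhood, rotamer_fits
from .errors import ClashscanError, VariantMismatchError
from .geometry import backbone_torsions, build_side_chain, relative_accessibility, sasa
from .rotamer_library import Rotamer, RotamerLibrary, candidate_rotamers, load_default_library
from .structure_model import ResidueSite, Structure, Variant, get_site

__all__ = [
    "DecisionParams",
    "Prediction",
    "BatchResult",
    "prepare_structure",
    "apply_assumptions",
    "predict",
    "predict_all",
]


@dataclass
class DecisionParams:
    """Tunables of the fast-path assumption rules."""

    accessibility_threshold: float = 0.5
    min_sidechain_length: int = 3
    sidechain_size: dict[str, int] = field(default_factory=lambda: dict(SIDECHAIN_SIZE))
    branched_exceptions: frozenset[str] = frozenset({"V", "L", "I", "T"})
    min_frequency: float = 0.0


@dataclass
class Prediction:
    """Per-variant verdict and the path that decided it."""

    variant: Variant
    verdict: str  # "fits" | "clash"
    decision_path: str  # accessible_rule | glycine_rule | smaller_rule |
    #                     rotamer_fit | no_rotamer_fits
    fitting_rotamer: Rotamer | None = None
    clashes: list[ClashResult] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.verdict == "clash" and self.decision_path != "no_rotamer_fits":
            raise ValueError("a clash verdict can only come from exhausted rotamers")
        if self.fitting_rotamer is not None and self.verdict != "fits":
            raise ValueError("a fitting rotamer implies a fits verdict")


@dataclass
class BatchResult:
    """predict_all output: per-variant predictions with isolated errors."""

    results: list[tuple[Variant, Prediction | None, Exception | None]]

    @property
    def predictions(self) -> list[Prediction]:
        return [p for _, p, _ in self.results if p is not None]

    @property
    def errors(self) -> list[tuple[Variant, Exception]]:
        return [(v, e) for v, _, e in self.results if e is not None]


def prepare_structure(structure: Structure, probe: float = 1.4, n_points: int = 960) -> None:
    """Compute backbone torsions and side-chain relative accessibility
    for every site, once per structure; results are cached on the sites."""
    if structure._prepared:
        return
    backbone_torsions(structure)
    abs_acc = sasa(structure, probe=probe, n_points=n_points)
    for res in structure.residues:
        if res.res_type == "G":
            res.sidechain_rel_acc = 0.0
        else:
            res.sidechain_rel_acc = relative_accessibility(abs_acc[res.key], res.res_type)
    structure._prepared = True


def apply_assumptions(site: ResidueSite, to_aa: str, params: DecisionParams) -> str | None:
    """Fast-path screen; returns the rule name that grants a fit, or None
    when the substitution must go to rotamer testing."""
    size = params.sidechain_size
    if to_aa == "G":
        return "glycine_rule"
    if (
        site.sidechain_rel_acc is not None
        and site.sidechain_rel_acc >= params.accessibility_threshold
        and size[site.res_type] >= params.min_sidechain_length
    ):
        return "accessible_rule"
    if size[to_aa] < size[site.res_type] and to_aa not in params.branched_exceptions:
        return "smaller_rule"
    return None


_PROLINE_WARNING = (
    "proline substitution: backbone rearrangement is not modelled, "
    "clash predictions for proline are over-called"
)


def predict(
    structure: Structure,
    variant: Variant,
    lib: RotamerLibrary | None = None,
    cparams: ClashParams | None = None,
    dparams: DecisionParams | None = None,
    site: ResidueSite | None = None,
    env_atoms=None,
) -> Prediction:
    """Predict whether one substitution can be sterically accommodated.

    ``site`` and ``env_atoms`` let batch callers reuse the resolved site
    and its precomputed neighborhood.
    """
    lib = load_default_library() if lib is None else lib
    cparams = ClashParams() if cparams is None else cparams
    dparams = DecisionParams() if dparams is None else dparams
    if variant.to_aa is None:
        raise ClashscanError("predict() needs a concrete target amino acid")
    to_aa = variant.to_aa
    if site is None:
        site = get_site(structure, variant.chain_id, variant.seq_number, variant.insertion_code)
    if variant.from_aa is not None and variant.from_aa != site.res_type:
        raise VariantMismatchError(
            f"variant says {variant.from_aa} at {variant.chain_id}:"
            f"{variant.seq_number}{variant.insertion_code} but structure has "
            f"{site.res_type}"
        )
    prepare_structure(structure)

    warnings = [_PROLINE_WARNING] if to_aa == "P" else []

    rule = apply_assumptions(site, to_aa, dparams)
    if rule is not None:
        return Prediction(variant, "fits", rule, warnings=warnings)

    if to_aa == "A":
        # a lone C-beta is never clash-tested, so alanine always fits
        return Prediction(variant, "fits", "rotamer_fit", warnings=warnings)

    if env_atoms is None:
        env_atoms = neighborhood(structure, site, cparams)
    rotamers = candidate_rotamers(lib, to_aa, site.phi, site.psi, dparams.min_frequency)
    best: tuple[int, float, list[ClashResult]] | None = None
    for rot in rotamers:
        atoms = build_side_chain(site, to_aa, rot.chi)
        fits, clashes = rotamer_fits(
            structure, site, atoms, env_atoms, cparams, collect_all=True
        )
        if fits:
            return Prediction(
                variant, "fits", "rotamer_fit", fitting_rotamer=rot, warnings=warnings
            )
        # best rotamer for reporting: fewest clashes, tie -> most frequent
        key = (len(clashes), -rot.frequency)
        if best is None or key < (best[0], best[1]):
            best = (len(clashes), -rot.frequency, clashes)
    return Prediction(
        variant,
        "clash",
        "no_rotamer_fits",
        clashes=best[2] if best is not None else [],
        warnings=warnings,
    )


def expand_variant(variant: Variant, site_res_type: str) -> list[Variant]:
    """Expand a position-only variant to all 19 substitutions, in fixed
    alphabetical one-letter order."""
    if not variant.is_position_only:
        return [variant]
    return [
        Variant(
            variant.chain_id,
            variant.seq_number,
            variant.insertion_code,
            from_aa=site_res_type,
            to_aa=aa,
        )
        for aa in sorted(STANDARD_AA1)
        if aa != site_res_type
    ]


def predict_all(
    structure: Structure,
    variants: list[Variant],
    lib: RotamerLibrary | None = None,
    cparams: ClashParams | None = None,
    dparams: DecisionParams | None = None,
) -> BatchResult:
    """Predict a batch; per-variant errors are recorded, not fatal.

    Position-only variants expand to all 19 non-identical substitutions;
    the site's neighborhood and torsions are computed once and reused.
    Output order follows input order (expansions in alphabetical order).
    """
    lib = load_default_library() if lib is None else lib
    cparams = ClashParams() if cparams is None else cparams
    dparams = DecisionParams() if dparams is None else dparams
    results: list[tuple[Variant, Prediction | None, Exception | None]] = []
    env_cache: dict[tuple[str, int, str], list] = {}
    for var in variants:
        try:
            site = get_site(structure, var.chain_id, var.seq_number, var.insertion_code)
        except ClashscanError as exc:
            results.append((var, None, exc))
            continue
        for sub in expand_variant(var, site.res_type):
            try:
                key = site.key
                if key not in env_cache:
                    env_cache[key] = neighborhood(structure, site, cparams)
                pred = predict(
                    structure, sub, lib, cparams, dparams,
                    site=site, env_atoms=env_cache[key],
                )
                results.append((sub, pred, None))
            except ClashscanError as exc:
                results.append((sub, None, exc))
    return BatchResult(results)
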