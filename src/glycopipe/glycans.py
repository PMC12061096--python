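"""Glycan compositions, decoy databases, and modification-class rules.

A glycan is represented by its monosaccharide composition only — the
fragmentation data underlying this pipeline cannot resolve linkage or
branching, so two structural isomers with the same composition are one
entity here.  Compositions are written in the search-engine dialect
``Symbol(count)``, e.g. ``HexNAc(4)Hex(5)Fuc(1)NeuAc(2)``; a bare symbol
means count 1 (glycation, the non-enzymatic attachment of a single
hexose to lysine, is the composition ``Hex``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GlycanComposition",
    "GlycanDatabase",
    "GlycanParseError",
    "MONOSACCHARIDE_MASSES",
    "parse_glycan_composition",
    "glycan_monoisotopic_mass",
    "load_glycan_database",
    "generate_decoy_glycans",
    "classify_modification",
    "validate_nglyco_motif",
    "builtin_glycan_database",
]

#: Monoisotopic residue masses (Da) of the glycan building blocks, i.e. the
#: free monosaccharide minus one water, summed from CODATA atomic masses.
MONOSACCHARIDE_MASSES: dict[str, float] = {
    "Hex": 162.0528234,      # C6H10O5
    "HexNAc": 203.0793725,   # C8H13NO5
    "Fuc": 146.0579088,      # C6H10O4 (deoxyhexose)
    "NeuAc": 291.0954165,    # C11H17NO8
    "NeuGc": 307.0903311,    # C11H17NO9
    "Pent": 132.0422588,     # C5H8O4
    "HexA": 176.0320880,     # C6H8O6
    "Sulfo": 79.9568146,     # SO3
    "Phospho": 79.9663305,   # HPO3
}

#: Fixed symbol order used by the canonical string rendering.
CANONICAL_ORDER: tuple[str, ...] = (
    "HexNAc", "Hex", "Fuc", "NeuAc", "NeuGc", "Pent", "HexA", "Sulfo", "Phospho",
)

_RANK = {s: i for i, s in enumerate(CANONICAL_ORDER)}


class GlycanParseError(ValueError):
    """Raised when a composition string cannot be parsed."""


@dataclass(frozen=True)
class GlycanComposition:
    """An immutable monosaccharide-count vector plus a decoy flag.

    Hashable and order-canonical: equal compositions render to identical
    strings regardless of input token order.
    """

    items: tuple[tuple[str, int], ...]
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("composition must contain at least one monosaccharide")
        for sym, n in self.items:
            if n < 1:
                raise ValueError(f"count for {sym} must be >= 1, got {n}")
        ordered = tuple(sorted(self.items, key=lambda kv: _RANK.get(kv[0], 99)))
        object.__setattr__(self, "items", ordered)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], is_decoy: bool = False) -> "GlycanComposition":
        return cls(tuple((s, int(n)) for s, n in counts.items() if n), is_decoy=is_decoy)

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.items)

    def same_counts(self, other: "GlycanComposition") -> bool:
        """Count-identity, ignoring the decoy flag."""
        return self.items == other.items

    def render(self) -> str:
        """Canonical ``Symbol(count)`` string in fixed symbol order."""
        return "".join(f"{s}({n})" for s, n in self.items)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @property
    def is_single_hexose(self) -> bool:
        """True for the bare-hexose composition that marks glycation."""
        return self.items == (("Hex", 1),)


# longest-first alternation so HexNAc/HexA are not swallowed by Hex
_SYMBOL_ALT = "|".join(sorted(MONOSACCHARIDE_MASSES, key=len, reverse=True))
_TOKEN_RE = re.compile(rf"({_SYMBOL_ALT})(?:\((-?\d+)\))?")
_ANY_TOKEN_RE = re.compile(r"([A-Za-z][a-z0-9]*)(?:\((-?\d+)\))?")


def parse_glycan_composition(text: str, is_decoy: bool = False) -> GlycanComposition:
    """Parse a ``Symbol(count)`` composition string.

    A bare symbol means count 1.  Unknown symbols and non-positive counts
    are rejected with a :class:`GlycanParseError` naming the offending
    token.
    """
    if not text or not text.strip():
        raise GlycanParseError("empty composition string")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            bad = _ANY_TOKEN_RE.match(text, pos)
            token = bad.group(1) if bad else text[pos:]
            raise GlycanParseError(f"unknown monosaccharide symbol {token!r} in {text!r}")
        sym, n_str = m.group(1), m.group(2)
        n = 1 if n_str is None else int(n_str)
        if n < 1:
            raise GlycanParseError(f"count {n} for {sym!r} must be positive in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return GlycanComposition.from_counts(counts, is_decoy=is_decoy)


def glycan_monoisotopic_mass(g: GlycanComposition | Mapping[str, int]) -> float:
    """Sum of count x monoisotopic residue mass over the composition.

    Accepts a raw count mapping as well; an empty mapping sums to 0.0.
    """
    counts = g.counts if isinstance(g, GlycanComposition) else dict(g)
    total = 0.0
    for sym, n in counts.items():
        try:
            total += n * MONOSACCHARIDE_MASSES[sym]
        except KeyError:
            raise KeyError(f"no monoisotopic mass known for symbol {sym!r}") from None
    return total


@dataclass
class GlycanDatabase:
    """Target and decoy glycan composition lists.

    Decoys count-identical to a target are invalid; the loader drops them
    with a warning.
    """

    targets: list[GlycanComposition] = field(default_factory=list)
    decoys: list[GlycanComposition] = field(default_factory=list)

    def __post_init__(self) -> None:
        target_keys = {t.items for t in self.targets}
        clashes = [d for d in self.decoys if d.items in target_keys]
        if clashes:
            raise ValueError(
                f"{len(clashes)} decoy composition(s) are count-identical to targets"
            )

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_decoys(self) -> int:
        return len(self.decoys)


def _read_composition_lines(path) -> list[str]:
    with open(path, "rt", encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]


def load_glycan_database(target_path, decoy_path=None) -> GlycanDatabase:
    """Load newline-delimited composition lists (``#`` comments tolerated).

    Entries are deduplicated within each list; a decoy count-identical to
    a target is dropped with a warning.  An empty target list is an error.
    """
    target_lines = _read_composition_lines(target_path)
    if not target_lines:
        raise ValueError(f"target glycan list {target_path} is empty")

    def _dedup(lines: Iterable[str], is_decoy: bool) -> list[GlycanComposition]:
        seen: dict[tuple, GlycanComposition] = {}
        for ln in lines:
            g = parse_glycan_composition(ln, is_decoy=is_decoy)
            seen.setdefault(g.items, g)
        return list(seen.values())

    targets = _dedup(target_lines, False)
    decoys: list[GlycanComposition] = []
    if decoy_path is not None:
        decoys = _dedup(_read_composition_lines(decoy_path), True)
        target_keys = {t.items for t in targets}
        n_before = len(decoys)
        decoys = [d for d in decoys if d.items not in target_keys]
        dropped = n_before - len(decoys)
        if dropped:
            warnings.warn(
                f"dropped {dropped} decoy glycan(s) count-identical to targets",
                stacklevel=2,
            )
    return GlycanDatabase(targets=targets, decoys=decoys)


def generate_decoy_glycans(
    targets: Sequence[GlycanComposition],
    n: int,
    seed: int | np.random.Generator = 0,
    max_attempts_per_decoy: int = 2000,
) -> list[GlycanComposition]:
    """Draw ``n`` decoy compositions mass-matched to the target mass range.

    Fallback for when no curated non-human decoy list is available.  Each
    decoy differs in counts from every target and has total mass within
    the [min, max] target mass range (widened by one hexose when the range
    is degenerate).  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not targets:
        raise ValueError("need at least one target composition")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    masses = [glycan_monoisotopic_mass(t) for t in targets]
    lo, hi = min(masses), max(masses)
    if hi - lo < MONOSACCHARIDE_MASSES["Hex"]:
        pad = MONOSACCHARIDE_MASSES["Hex"]
        lo, hi = lo - pad, hi + pad
    forbidden = {t.items for t in targets}
    symbols = ["HexNAc", "Hex", "Fuc", "NeuAc", "NeuGc", "Pent"]
    decoys: list[GlycanComposition] = []
    seen: set[tuple] = set()
    for _ in range(n):
        for attempt in range(max_attempts_per_decoy):
            counts = {
                "HexNAc": int(rng.integers(0, 7)),
                "Hex": int(rng.integers(0, 10)),
                "Fuc": int(rng.integers(0, 4)),
                "NeuAc": int(rng.integers(0, 5)),
                "NeuGc": int(rng.integers(0, 3)),
                "Pent": int(rng.integers(0, 3)),
            }
            counts = {s: c for s, c in counts.items() if c > 0}
            if not counts:
                continue
            g = GlycanComposition.from_counts(counts, is_decoy=True)
            if g.items in forbidden or g.items in seen:
                continue
            if not (lo <= glycan_monoisotopic_mass(g) <= hi):
                continue
            decoys.append(g)
            seen.add(g.items)
            break
        else:
            raise RuntimeError(
                f"could not generate decoy {len(decoys) + 1}/{n} within "
                f"{max_attempts_per_decoy} attempts; relax the mass constraint"
            )
    return decoys


class ModificationError(ValueError):
    """Raised when a site/glycan pairing violates the modification rules."""


def classify_modification(
    site_residue: str, g: GlycanComposition, motif_ok: bool | None = None
) -> str:
    """Classify a modified site as ``"glycation"`` or ``"glycosylation"``.

    Glycation is the single hexose on lysine; N-glycosylation is any
    composition on an asparagine whose sequon (N-X-S/T, X != P) holds,
    which the caller asserts via ``motif_ok``.
    """
    if site_residue == "K":
        if not g.is_single_hexose:
            raise ModificationError(
                f"lysine carries only the single-hexose glycation adduct, got {g.render()}"
            )
        return "glycation"
    if site_residue == "N":
        if not motif_ok:
            raise ModificationError("asparagine site lacks a valid N-X-S/T sequon")
        return "glycosylation"
    raise ModificationError(f"modified residue must be K or N, got {site_residue!r}")


def validate_nglyco_motif(protein_sequence: str, site_1based: int) -> bool:
    """True iff the N-X-S/T sequon (X != P) holds at a 1-based Asn site."""
    if not 1 <= site_1based <= len(protein_sequence):
        raise IndexError(
            f"site {site_1based} out of bounds for sequence of length {len(protein_sequence)}"
        )
    if protein_sequence[site_1based - 1] != "N":
        raise ValueError(f"residue at site {site_1based} is not N")
    if site_1based + 2 > len(protein_sequence):
        return False
    x, third = protein_sequence[site_1based], protein_sequence[site_1based + 1]
    return x != "P" and third in ("S", "T")


def builtin_glycan_database(n_targets: int = 141, n_decoys: int = 141, seed: int = 20) -> GlycanDatabase:
    """A synthetic stand-in glycan panel of plausible serum N-glycans.

    Enumerates biantennary-to-tetraantennary complex/hybrid/high-mannose
    compositions in a deterministic order and keeps the first
    ``n_targets``; decoys are mass-matched random compositions.  This is a
    synthetic panel for simulation and testing, not the curated human
    serum list a real study would supply.
    """
    combos: list[GlycanComposition] = []
    # high-mannose series
    for hex_n in range(5, 13):
        combos.append(GlycanComposition.from_counts({"HexNAc": 2, "Hex": hex_n}))
    # complex/hybrid series
    for hexnac in range(3, 7):
        for hexn in range(3, 8):
            for fuc in range(0, 2):
                for neuac in range(0, min(hexnac - 1, 4) + 1):
                    combos.append(
                        GlycanComposition.from_counts(
                            {"HexNAc": hexnac, "Hex": hexn, "Fuc": fuc, "NeuAc": neuac}
                        )
                    )
    targets = combos[:n_targets]
    if len(targets) < n_targets:
        raise ValueError(f"can only enumerate {len(targets)} built-in targets")
    decoys = generate_decoy_glycans(targets, n_decoys, seed=seed)
    return GlycanDatabase(targets=targets, decoys=decoys)
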