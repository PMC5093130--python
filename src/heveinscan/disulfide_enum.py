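"""Disulfide-connectivity enumeration and energy ranking.

A candidate disulfide connectivity for a peptide with 2k cysteines is a
perfect matching of the cysteines into k bonds.  Cysteines are
addressed by roman-numeral labels (I, II, ...) in sequence order, so
the module is sequence-agnostic; positions map to labels through
:class:`heveinscan.hevein_core.CysFramework`.

With an experimentally fixed bond (e.g. CysII-CysV pinned by an
unambiguous NOE) the remaining 2k-2 cysteines admit (2k-3)!! matchings:
for eight cysteines with one bond fixed, 15 patterns; unconstrained,
7!! = 105.  Pattern energies come from an external structure
calculation and are only ranked here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hevein_core import ROMAN


@dataclass(frozen=True)
class DisulfidePattern:
    """One perfect matching, canonically ordered.

    Bonds are stored as (label_a, label_b) pairs with a before b in
    sequence order, sorted by the first label's sequence rank.
    """

    bonds: tuple[tuple[str, str], ...]

    def __str__(self) -> str:
        return ", ".join(f"{a}-{b}" for a, b in self.bonds)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(l for bond in self.bonds for l in bond)


@dataclass(frozen=True)
class PatternEnergy:
    pattern: DisulfidePattern
    energy: float  # kcal/mol, externally supplied


def _canonical(bonds: list[tuple[str, str]]) -> DisulfidePattern:
    rank = {lab: i for i, lab in enumerate(ROMAN)}
    ordered = [tuple(sorted(b, key=rank.__getitem__)) for b in bonds]
    ordered.sort(key=lambda b: rank[b[0]])
    return DisulfidePattern(tuple(ordered))


def enumerate_patterns(
    n_cys: int, fixed: set[tuple[str, str]] | None = None
) -> list[DisulfidePattern]:
    """All perfect matchings of ``n_cys`` labelled cysteines.

    ``fixed`` bonds must appear in every pattern.  Output is canonical
    and deterministically ordered (lexicographic by sequence rank);
    the count is (2k-1)!! for 2k unconstrained cysteines.
    """
    if n_cys <= 0 or n_cys % 2:
        raise ValueError(f"n_cys must be a positive even integer, got {n_cys}")
    labels = ROMAN[:n_cys]
    rank = {lab: i for i, lab in enumerate(labels)}
    fixed_bonds: list[tuple[str, str]] = []
    used: set[str] = set()
    for bond in sorted(fixed or (), key=lambda b: min(rank.get(x, -1) for x in b)):
        a, b = bond
        for lab in (a, b):
            if lab not in rank:
                raise ValueError(f"fixed pair {bond} uses label {lab!r} outside I..{labels[-1]}")
        if a == b:
            raise ValueError(f"self-pair {bond} not allowed")
        if a in used or b in used:
            raise ValueError(f"conflicting fixed pairs: label reused in {bond}")
        used.update((a, b))
        fixed_bonds.append(bond)
    free = [lab for lab in labels if lab not in used]

    patterns: list[DisulfidePattern] = []

    def recurse(remaining: list[str], acc: list[tuple[str, str]]) -> None:
        if not remaining:
            patterns.append(_canonical(fixed_bonds + acc))
            return
        first, rest = remaining[0], remaining[1:]
        for i, partner in enumerate(rest):
            recurse(rest[:i] + rest[i + 1 :], acc + [(first, partner)])

    recurse(free, [])
    patterns.sort(key=lambda p: [ROMAN.index(l) for bond in p.bonds for l in bond])
    return patterns


def rank_patterns(
    patterns: list[DisulfidePattern], energies: dict[DisulfidePattern, float]
) -> list[PatternEnergy]:
    """Sort patterns by ascending energy; ties keep canonical order (stable)."""
    ranked = []
    for p in patterns:
        if p not in energies:
            raise ValueError(f"no energy supplied for pattern {{{p}}}")
        ranked.append(PatternEnergy(p, energies[p]))
    ranked.sort(key=lambda pe: pe.energy)
    return ranked
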