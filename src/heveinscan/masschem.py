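"""Peptide mass arithmetic, alkylation shifts and isoelectric point.

Covers the intact-mass bookkeeping used when characterising
cysteine-rich peptides by MALDI-TOF: monoisotopic/average mass in the
reduced, disulfide-bonded or S-alkylated state, [M+H]+ adducts,
inference of the cysteine count from the reduction/alkylation mass
shift (~58 Da per Cys), and Henderson-Hasselbalch net charge / pI.

Each disulfide bond removes two hydrogen atoms relative to the reduced
peptide; each S-alkylation adds the reagent adduct to a free thiol.
A shift measured against the *native* (disulfide-bonded) species
therefore includes the hydrogen regained on reduction in addition to
the reagent mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from pyteomics import mass as _ptmass

PROTON = 1.007276
HYDROGEN = 1.007825
WATER_MONO = 18.010565
WATER_AVG = 18.0153

#: carboxymethyl (iodoacetic acid), carbamidomethyl (iodoacetamide) and the
#: nominal 58 Da per Cys used for quick integer arithmetic on MALDI shifts
ALKYLATION_REAGENTS = {
    "carboxymethyl": 58.00548,
    "carbamidomethyl": 57.02146,
    "nominal": 58.0,
}

_STD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: residue (amino-acid minus water) masses from the pyteomics composition
#: tables: residue -> (monoisotopic, average) Da
RESIDUE_MASSES: dict[str, tuple[float, float]] = {
    aa: (
        _ptmass.calculate_mass(parsed_sequence=[aa], average=False),
        _ptmass.calculate_mass(parsed_sequence=[aa], average=True),
    )
    for aa in _STD_RESIDUES
}


@dataclass(frozen=True)
class AlkylationModel:
    """Alkylation reagent and the reference state of the measured shift."""

    reagent: str = "carboxymethyl"
    reference_state: str = "reduced"  # or "native"

    @property
    def reagent_mass(self) -> float:
        try:
            return ALKYLATION_REAGENTS[self.reagent]
        except KeyError:
            raise ValueError(f"unknown reagent {self.reagent!r}") from None

    @property
    def per_cys_shift(self) -> float:
        """Observed mass increase per cysteine for this reference state."""
        if self.reference_state == "reduced":
            return self.reagent_mass
        if self.reference_state == "native":
            # reduction returns one H per half-cystine before alkylation
            return self.reagent_mass + HYDROGEN
        raise ValueError(f"unknown reference state {self.reference_state!r}")


@dataclass(frozen=True)
class MassResult:
    mass: float
    kind: str  # monoisotopic | average
    state: str  # e.g. "reduced", "4 disulfides", "alkylated"

    @property
    def mh_plus(self) -> float:
        return self.mass + PROTON


def peptide_mass(
    seq: str,
    kind: str = "monoisotopic",
    n_disulfides: int = 0,
    alkylation: AlkylationModel | None = None,
) -> MassResult:
    """Neutral peptide mass in a given disulfide/alkylation state.

    mass = sum(residue masses) + water - 2*n_disulfides*H
    (+ n_cys * reagent mass when alkylated).  Alkylation presumes free
    thiols, so it cannot be combined with disulfides.
    """
    if kind not in ("monoisotopic", "average"):
        raise ValueError(f"kind must be monoisotopic or average, got {kind!r}")
    col = 0 if kind == "monoisotopic" else 1
    total = WATER_MONO if kind == "monoisotopic" else WATER_AVG
    n_cys = 0
    for res in seq:
        try:
            total += RESIDUE_MASSES[res][col]
        except KeyError:
            raise ValueError(f"unknown residue {res!r} (not a standard amino acid)") from None
        if res == "C":
            n_cys += 1
    if n_disulfides < 0 or n_disulfides > n_cys // 2:
        raise ValueError(
            f"n_disulfides={n_disulfides} impossible for {n_cys} cysteines"
        )
    if alkylation is not None:
        if n_disulfides:
            raise ValueError("alkylation applies to free thiols only (n_disulfides must be 0)")
        total += n_cys * alkylation.reagent_mass
        state = "alkylated"
    elif n_disulfides:
        total -= 2 * n_disulfides * HYDROGEN
        state = f"{n_disulfides} disulfides"
    else:
        state = "reduced"
    return MassResult(total, kind, state)


def mh_plus(mass: float) -> float:
    """Singly protonated adduct mass [M+H]+."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return mass + PROTON


def alkylation_shift(n_cys: int, model: AlkylationModel | None = None) -> float:
    """Total mass increase for S-alkylating ``n_cys`` cysteines."""
    if n_cys < 0:
        raise ValueError("n_cys must be >= 0")
    model = model or AlkylationModel()
    return n_cys * model.per_cys_shift


def cys_count_from_shift(
    observed_shift: float,
    model: AlkylationModel | None = None,
    tolerance_fraction: float = 0.25,
) -> int:
    """Infer the cysteine count from a reduction/alkylation mass shift.

    Rounds observed_shift / per-Cys shift to the nearest integer and
    rejects ambiguous shifts whose residual exceeds
    ``tolerance_fraction`` of the per-Cys shift.
    """
    if observed_shift < 0:
        raise ValueError("observed shift must be >= 0")
    model = model or AlkylationModel()
    per = model.per_cys_shift
    n = round(observed_shift / per)
    residual = abs(observed_shift - n * per)
    if residual > tolerance_fraction * per:
        lo, hi = math.floor(observed_shift / per), math.ceil(observed_shift / per)
        raise ValueError(
            f"ambiguous shift {observed_shift} Da: residual {residual:.3f} Da "
            f"exceeds tolerance; candidates {lo} or {hi} cysteines"
        )
    return int(n)


# ---------------------------------------------------------------------------
# charge and isoelectric point

#: EMBOSS pKa set (as used by `iep`): N/C termini plus the seven ionisable
#: side chains.  Swappable via the ``pka`` argument.
EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_BASIC = {"Nterm", "H", "K", "R"}
_ACIDIC = {"Cterm", "C", "D", "E", "Y"}


def net_charge(seq: str, pH: float, pka: dict[str, float] | None = None) -> float:
    """Henderson-Hasselbalch net charge at a given pH.

    Positive groups contribute 1/(1+10^(pH-pKa)), negative groups
    -1/(1+10^(pKa-pH)); strictly decreasing in pH.
    """
    pka = pka or EMBOSS_PKA
    bad = set(seq) - set(_STD_RESIDUES)
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)} in sequence")
    groups = ["Nterm", "Cterm"] + [res for res in seq if res in pka]
    charge = 0.0
    for g in groups:
        if g in _BASIC:
            charge += 1.0 / (1.0 + 10 ** (pH - pka[g]))
        else:
            charge -= 1.0 / (1.0 + 10 ** (pka[g] - pH))
    return charge


def isoelectric_point(
    seq: str,
    pka: dict[str, float] | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> float:
    """pH at which the net charge vanishes, located by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        c = net_charge(seq, mid, pka)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("pI bisection did not converge")
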