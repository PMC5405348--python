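"""Physicochemical descriptors of candidate proteins (ProtParam-equivalent).

Nine descriptors characterise each candidate: residue count, average
molecular weight, theoretical pI, counts of negatively (D+E) and positively
(K+R) charged residues, molar extinction coefficients at 280 nm (reduced and
cystine forms), Guruprasad instability index, Ikai aliphatic index and
Kyte-Doolittle GRAVY. All are computed from the published constant tables in
:mod:`nitriminer._tables`; nothing is delegated to an external service.
"""

from __future__ import annotations

import dataclasses

from . import _tables as T
from .seqio import ProteinSequence

INSTABILITY_STABLE_THRESHOLD = 40.0  # below: conventionally "stable"


@dataclasses.dataclass(frozen=True)
class PropertyProfile:
    """The nine descriptors for one protein."""

    protein_id: str
    n_residues: int
    mol_weight: float
    pi: float
    ncr: int
    pcr: int
    ext_coeff_reduced: float
    ext_coeff_cystine: float
    instability_index: float
    aliphatic_index: float
    gravy: float

    @property
    def stable(self) -> bool:
        return self.instability_index < INSTABILITY_STABLE_THRESHOLD


def molecular_weight(p: ProteinSequence) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    return sum(T.RESIDUE_MASS[a] for a in p.seq) + T.WATER_MASS


def net_charge(p: ProteinSequence, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (Bjellqvist pK set).

    Terminal pK values are corrected for the identity of the terminal
    residues, as ProtParam does.
    """
    seq = p.seq
    pos_pks = dict(T.POSITIVE_PKS)
    neg_pks = dict(T.NEGATIVE_PKS)
    pos_pks["Nterm"] = T.PK_NTERMINAL.get(seq[0], pos_pks["Nterm"])
    neg_pks["Cterm"] = T.PK_CTERMINAL.get(seq[-1], neg_pks["Cterm"])
    counts = {a: seq.count(a) for a in "DECYHKR"}
    charge = 1.0 / (1.0 + 10 ** (ph - pos_pks["Nterm"]))
    for aa in "HKR":
        charge += counts[aa] / (1.0 + 10 ** (ph - pos_pks[aa]))
    charge -= 1.0 / (1.0 + 10 ** (neg_pks["Cterm"] - ph))
    for aa in "DECY":
        charge -= counts[aa] / (1.0 + 10 ** (neg_pks[aa] - ph))
    return charge


def theoretical_pi(p: ProteinSequence, tol: float = 0.005) -> float:
    """pH of zero net charge, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(p, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def charged_residue_counts(p: ProteinSequence) -> tuple[int, int]:
    """(NCR, PCR) = (#D + #E, #K + #R); His excluded by convention."""
    seq = p.seq
    return seq.count("D") + seq.count("E"), seq.count("K") + seq.count("R")


def extinction_coefficient(p: ProteinSequence) -> tuple[float, float]:
    """(reduced, cystine) molar extinction at 280 nm, Gill-von Hippel."""
    seq = p.seq
    reduced = T.EXT_TRP * seq.count("W") + T.EXT_TYR * seq.count("Y")
    cystine = reduced + T.EXT_CYSTINE * (seq.count("C") // 2)
    return float(reduced), float(cystine)


def instability_index(p: ProteinSequence) -> float:
    """(10/L) x sum of dipeptide instability weights along the sequence."""
    seq = p.seq
    if len(seq) < 2:
        raise ValueError("instability index requires length >= 2")
    total = sum(T.DIWV[seq[i]][seq[i + 1]] for i in range(len(seq) - 1))
    return 10.0 * total / len(seq)


def aliphatic_index(p: ProteinSequence) -> float:
    """X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu)), X in mole percent."""
    seq = p.seq
    n = len(seq)
    return 100.0 * (
        seq.count("A")
        + T.ALIPHATIC_COEF_VAL * seq.count("V")
        + T.ALIPHATIC_COEF_ILE_LEU * (seq.count("I") + seq.count("L"))
    ) / n


def gravy(p: ProteinSequence) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle score."""
    return sum(T.KYTE_DOOLITTLE[a] for a in p.seq) / len(p.seq)


def property_profile(p: ProteinSequence) -> PropertyProfile:
    ncr, pcr = charged_residue_counts(p)
    red, cys = extinction_coefficient(p)
    return PropertyProfile(
        protein_id=p.id,
        n_residues=len(p),
        mol_weight=molecular_weight(p),
        pi=theoretical_pi(p),
        ncr=ncr,
        pcr=pcr,
        ext_coeff_reduced=red,
        ext_coeff_cystine=cys,
        instability_index=instability_index(p),
        aliphatic_index=aliphatic_index(p),
        gravy=gravy(p),
    )


def profile_table(profiles) -> list[dict]:
    """Rows mirroring the standard comparison-chart layout."""
    return [
        {
            "protein_id": pr.protein_id,
            "n_residues": pr.n_residues,
            "mol_weight_da": round(pr.mol_weight, 1),
            "theoretical_pi": round(pr.pi, 2),
            "ncr": pr.ncr,
            "pcr": pr.pcr,
            "ext_coeff_reduced": pr.ext_coeff_reduced,
            "ext_coeff_cystine": pr.ext_coeff_cystine,
            "instability_index": round(pr.instability_index, 2),
            "stable": pr.stable,
            "aliphatic_index": round(pr.aliphatic_index, 2),
            "gravy": round(pr.gravy, 3),
        }
        for pr in profiles
    ]
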