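"""Theoretical isoelectric point and molecular weight.

The pI is the pH at which the protein's net charge, modeled by
Henderson–Hasselbalch terms over the ionizable groups (termini plus the
side chains of C, D, E, H, K, R, Y), crosses zero. The pK set is the
Bjellqvist set used by the ExPASy Compute pI/Mw tool, packaged as
``data/pk_bjellqvist.yaml``; where that set provides an N- or C-terminal
variant for the terminal residue, the variant applies. Net charge is
strictly decreasing in pH, so the zero is unique and bisection on [0, 14]
converges unconditionally.

Molecular weight is the sum of average isotopic residue masses plus one
water molecule (``data/masses_average.yaml``), reported in Da.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .seqio import PROTEIN_ALPHABET


@dataclass(frozen=True)
class PkTable:
    positive: dict[str, float]  # Nterm + basic side chains
    negative: dict[str, float]  # Cterm + acidic side chains
    nterm_by_residue: dict[str, float]
    cterm_by_residue: dict[str, float]


@dataclass(frozen=True)
class MassTable:
    residues: dict[str, float]
    water: float


def _load_yaml(name: str, path: str | Path | None) -> dict:
    if path is None:
        text = resources.files("kinfamscan.data").joinpath(name).read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def load_pk_table(path: str | Path | None = None) -> PkTable:
    raw = _load_yaml("pk_bjellqvist.yaml", path)
    table = PkTable(raw["positive"], raw["negative"],
                    raw.get("nterm_by_residue", {}),
                    raw.get("cterm_by_residue", {}))
    for group in (table.positive, table.negative,
                  table.nterm_by_residue, table.cterm_by_residue):
        for key, pk in group.items():
            if not 0 < pk < 14:
                raise ValueError(f"pK out of range for {key}: {pk}")
    return table


def load_mass_table(path: str | Path | None = None) -> MassTable:
    raw = _load_yaml("masses_average.yaml", path)
    if any(m <= 0 for m in raw["residues"].values()) or raw["water"] <= 0:
        raise ValueError("masses must be positive")
    return MassTable(raw["residues"], raw["water"])


def _check_protein(protein: str) -> None:
    if not protein:
        raise ValueError("empty protein sequence")
    bad = set(protein) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")


def net_charge(protein: str, pH: float, pk: PkTable | None = None) -> float:
    """Net charge at the given pH.

    Positive groups (N-terminus, H, K, R) contribute 1/(1+10^(pH-pK));
    negative groups (C-terminus, C, D, E, Y) contribute -1/(1+10^(pK-pH)).
    """
    _check_protein(protein)
    if pk is None:
        pk = load_pk_table()
    comp = Counter(protein)
    charge = 0.0
    nterm_pk = pk.nterm_by_residue.get(protein[0], pk.positive["Nterm"])
    charge += 1.0 / (1.0 + 10 ** (pH - nterm_pk))
    for res in "HKR":
        if comp[res]:
            charge += comp[res] / (1.0 + 10 ** (pH - pk.positive[res]))
    cterm_pk = pk.cterm_by_residue.get(protein[-1], pk.negative["Cterm"])
    charge -= 1.0 / (1.0 + 10 ** (cterm_pk - pH))
    for res in "CDEY":
        if comp[res]:
            charge -= comp[res] / (1.0 + 10 ** (pk.negative[res] - pH))
    return charge


def isoelectric_point(protein: str, pk: PkTable | None = None,
                      tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    Iterates until the bracketing interval is below ``tol`` AND the
    midpoint charge magnitude is below ``tol`` (the interval condition
    alone can leave a visible charge on lysine-rich sequences, the
    charge condition alone stops early on shallow curves); every protein
    has both termini, so an ionizable group always exists and the charge
    is strictly decreasing in pH.
    """
    if pk is None:
        pk = load_pk_table()
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(100):
        mid = (lo + hi) / 2
        q = net_charge(protein, mid, pk)
        if hi - lo < tol and abs(q) < tol:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def molecular_weight(protein: str, masses: MassTable | None = None) -> float:
    """Sum of average residue masses plus one water, in Da."""
    _check_protein(protein)
    if masses is None:
        masses = load_mass_table()
    try:
        return sum(masses.residues[r] for r in protein) + masses.water
    except KeyError as exc:  # pragma: no cover - guarded by _check_protein
        raise ValueError(f"unknown residue {exc.args[0]!r}") from exc


def protein_parameters(entries, pk: PkTable | None = None,
                       masses: MassTable | None = None) -> list[dict]:
    """Per-protein report rows: id, AA count, pI (2 dp), Mw in kDa (2 dp)."""
    pk = pk or load_pk_table()
    masses = masses or load_mass_table()
    rows = []
    for e in entries:
        rows.append({
            "id": e.id,
            "AA": len(e.sequence),
            "pI": round(isoelectric_point(e.sequence, pk), 2),
            "Mw_kDa": round(molecular_weight(e.sequence, masses) / 1000.0, 2),
        })
    return rows
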