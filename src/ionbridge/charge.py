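"""Formal-charge bookkeeping for protein sequences and ion property ratios.

At pH 7.4, Asp and Glu side chains carry -1 and Lys and Arg +1; His
(side-chain pKa ~ 6) is neutral by default but can be counted positive.
Termini contribute +1 (N) and -1 (C) when requested. This is integer
bookkeeping at a stated pH, not a titration model.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
from Bio import SeqIO

NEGATIVE = set("DE")
POSITIVE = set("KR")
AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ChargeProfile:
    sequence: str
    per_residue: list
    n_negative: int
    n_positive: int
    net_side_chain_charge: int
    termini_included: bool
    pH: float

    @property
    def net_charge(self) -> int:
        return self.net_side_chain_charge  # termini already folded in if requested


def charge_profile(sequence: str, pH: float = 7.4,
                   count_his_positive: bool = False,
                   include_termini: bool = False) -> ChargeProfile:
    """Per-residue formal charges and aggregate counts.

    D,E -> -1; K,R -> +1; H -> +1 only if ``count_his_positive``. With
    ``include_termini`` the free N/C termini add +1/-1 to the net (they
    cancel for an intact peptide, but are tracked for consistency).
    """
    seq = sequence.strip().upper()
    per = []
    positive = set(POSITIVE) | ({"H"} if count_his_positive else set())
    for i, aa in enumerate(seq):
        if aa not in AMINO_ALPHABET:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
        per.append(-1 if aa in NEGATIVE else (1 if aa in positive else 0))
    n_neg = sum(1 for c in per if c < 0)
    n_pos = sum(1 for c in per if c > 0)
    net = n_pos - n_neg
    if include_termini and seq:
        net += 1 - 1  # +1 N-terminus, -1 C-terminus
    return ChargeProfile(seq, per, n_neg, n_pos, net, include_termini, pH)


def subsequence(sequence: str, start: int, end: int) -> str:
    """1-based inclusive residue span, e.g. (35, 64) -> 30 residues."""
    if not 1 <= start <= end <= len(sequence):
        raise ValueError(f"span {start}..{end} out of range for length {len(sequence)}")
    return sequence[start - 1:end]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def snap25b_sequence() -> str:
    """Bundled rat SNAP25B reference sequence (206 aa)."""
    with resources.files("ionbridge.data").joinpath("snap25b_rat.fasta").open() as fh:
        return str(next(SeqIO.parse(fh, "fasta")).seq)


# ---------------------------------------------------------------------------
# ion properties

@dataclass
class IonProperties:
    symbol: str
    charge: int
    crystal_radius_A: float
    viscosity_B_cm3_mol: float
    hydration_energy_kJ_mol: float
    coordination_number: int


def load_ion_table() -> pd.DataFrame:
    """Bundled ion property table (charge, Shannon crystal radius,
    Jones-Dole viscosity B, hydration free energy, coordination number)."""
    with resources.files("ionbridge.data").joinpath("ion_properties.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def charge_to_radius(ion: IonProperties) -> float:
    """Ion charge / crystal radius in e per Angstrom, the abscissa of the
    clustering-efficacy volcano plot."""
    if ion.crystal_radius_A <= 0:
        raise ValueError("crystal radius must be positive")
    return ion.charge / ion.crystal_radius_A


def ion_from_table(symbol: str, table: pd.DataFrame | None = None) -> IonProperties:
    table = load_ion_table() if table is None else table
    row = table[table["symbol"] == symbol]
    if row.empty:
        raise KeyError(f"ion {symbol!r} not in table")
    r = row.iloc[0]
    return IonProperties(r["symbol"], int(r["charge"]), float(r["crystal_radius_A"]),
                         float(r["viscosity_B_cm3_mol"]),
                         float(r["hydration_energy_kJ_mol"]),
                         int(r["coordination_number"]))


def charge_to_radius_table(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Table with a ``charge_to_radius`` column added, sorted descending."""
    table = load_ion_table() if table is None else table.copy()
    table = table.copy()
    table["charge_to_radius"] = table["charge"] / table["crystal_radius_A"]
    return table.sort_values("charge_to_radius", ascending=False).reset_index(drop=True)
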