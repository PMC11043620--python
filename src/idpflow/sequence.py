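"""Formal-charge bookkeeping for protein sequences.

Used to reproduce simulation-box neutralization counts: the number of
monovalent counterions equals the magnitude of the formal net charge of the
chain at neutral pH (Asp/Glu -1, Lys/Arg +1, His neutral; the free termini
cancel).
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["formal_net_charge", "neutralizing_counterions", "load_mature_sequence"]

_NEGATIVE = set("DE")
_POSITIVE = set("KR")
_VALID = set("ACDEFGHIKLMNPQRSTVWY")

# Optional local sequence store (plain FASTA) for offline lookups.
_DATA_DIR = Path(__file__).parent / "data"


def formal_net_charge(sequence: str) -> int:
    """Net formal charge at neutral pH (termini cancel; His neutral)."""
    seq = sequence.strip().upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"unknown residue code(s): {sorted(bad)}")
    return sum(c in _POSITIVE for c in seq) - sum(c in _NEGATIVE for c in seq)


def neutralizing_counterions(sequence: str) -> tuple[str, int]:
    """Species and count of monovalent ions needed to neutralize the chain."""
    z = formal_net_charge(sequence)
    return ("Na+", -z) if z < 0 else ("Cl-", z)


def load_mature_sequence(name: str, mature_length: int | None = None) -> str:
    """Load a stored one-letter sequence by accession/name from the packaged
    FASTA store; optionally truncate to the C-terminal ``mature_length``
    residues (removing an N-terminal transit peptide)."""
    path = _DATA_DIR / f"{name}.fasta"
    if not path.exists():
        raise FileNotFoundError(
            f"no packaged sequence for {name!r}; fetch it and place a FASTA "
            f"file at {path}")
    lines = path.read_text().splitlines()
    seq = "".join(line.strip() for line in lines if not line.startswith(">"))
    if mature_length is not None:
        seq = seq[-mature_length:]
    return seq
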