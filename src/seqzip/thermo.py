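"""Nearest-neighbor duplex thermodynamics.

Melting temperatures and hybridization free energies for short DNA duplexes,
computed from the unified DNA/DNA nearest-neighbor parameter set of Allawi &
SantaLucia (1997).  These drive two decisions elsewhere in the toolkit: arm
trimming during ligamer design (a Tm stopping criterion) and the
cognate/near-cognate free-energy gap screen.

Model
-----
For a duplex of ``N`` base pairs the enthalpy and entropy are sums over the
``N - 1`` dinucleotide stacks plus one initiation term per terminus (A·T and
G·C termini differ).  The melting temperature of a two-state duplex at total
strand concentration ``C_T`` is

    Tm = 1000 * dH / (dS + R * ln(C_T / x)) - 273.15

with ``R = 1.987 cal/(mol K)``, ``x = 4`` for non-self-complementary
sequences and ``x = 1`` (plus a symmetry entropy term) for self-complementary
ones.  Monovalent salt enters as the entropic correction
``dS += 0.368 * (N - 1) * ln[Na+]``.  Free energy at temperature ``T`` is
``dG = dH - T_K * dS / 1000`` in kcal/mol.

Mismatches in :func:`duplex_free_energy` are handled with a single uniform
destabilization penalty per affected stack (configurable); hybrid DNA:RNA
tables can be substituted via ``parameter_table_id``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .errors import AlignmentError, InvalidSequenceError

R_GAS = 1.987  # cal / (mol K)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def load_parameter_table(table_id: str) -> dict[str, tuple[float, float]]:
    """Load a nearest-neighbor parameter table shipped with the package.

    Returns a mapping ``key -> (delta_H kcal/mol, delta_S cal/mol/K)`` with
    the 16 dinucleotide stacks plus ``init_AT``, ``init_GC`` and ``sym``.
    """
    text = resources.files("seqzip").joinpath("data", f"{table_id}.tsv").read_text()
    table: dict[str, tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, dh, ds = line.split("\t")
        table[key] = (float(dh), float(ds))
    stacks = [a + b for a in "ACGT" for b in "ACGT"]
    missing = [k for k in stacks + ["init_AT", "init_GC"] if k not in table]
    if missing:
        raise ValueError(f"parameter table {table_id!r} missing entries: {missing}")
    return table


@dataclass(frozen=True)
class DuplexParams:
    """Conditions under which Tm and ΔG are evaluated.

    monovalent_salt : mol/L Na+ equivalent (> 0).
    oligo_conc : mol/L total strand concentration (> 0).
    temperature_for_dg : °C at which ΔG is reported.
    parameter_table_id : nearest-neighbor table resource name.
    mismatch_dg_penalty : kcal/mol added to ΔG per mismatched stack.
    """

    monovalent_salt: float = 0.05
    oligo_conc: float = 5e-7
    temperature_for_dg: float = 37.0
    parameter_table_id: str = "dna_unified_1997"
    mismatch_dg_penalty: float = 1.0

    def __post_init__(self) -> None:
        if self.monovalent_salt <= 0:
            raise ValueError("monovalent_salt must be > 0")
        if self.oligo_conc <= 0:
            raise ValueError("oligo_conc must be > 0")

    @property
    def table(self) -> dict[str, tuple[float, float]]:
        return load_parameter_table(self.parameter_table_id)


DEFAULT_PARAMS = DuplexParams()


@dataclass(frozen=True)
class DuplexEnergy:
    """ΔG (kcal/mol at the configured temperature) and Tm (°C) of one duplex."""

    delta_g: float
    tm: float


def _check_sequence(seq: str, min_len: int = 2) -> str:
    seq = seq.upper().replace("U", "T")
    if not set(seq) <= _DNA:
        bad = sorted(set(seq) - _DNA)
        raise InvalidSequenceError(f"non-ACGT characters in sequence: {bad}")
    if len(seq) < min_len:
        raise InvalidSequenceError(
            f"sequence of length {len(seq)} too short (need >= {min_len})"
        )
    return seq


def _init_key(base: str) -> str:
    return "init_AT" if base in "AT" else "init_GC"


def _perfect_sums(seq: str, table) -> tuple[float, float]:
    """(ΔH, ΔS) for a perfect duplex: stacks plus both terminal initiations."""
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = table[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = table[_init_key(terminal)]
        dh += h
        ds += s
    return dh, ds


def melting_temp(sequence: str, params: DuplexParams = DEFAULT_PARAMS) -> float:
    """Nearest-neighbor Tm (°C) of ``sequence`` against its perfect complement.

    Deterministic in the sequence and ``params``; invariant under reverse
    complement of the input (duplex symmetry).
    """
    seq = _check_sequence(sequence)
    table = params.table
    dh, ds = _perfect_sums(seq, table)
    selfcomp = seq == reverse_complement(seq)
    if selfcomp:
        h, s = table.get("sym", (0.0, 0.0))
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(params.monovalent_salt)
    x = 1.0 if selfcomp else 4.0
    denom = ds + R_GAS * math.log(params.oligo_conc / x)
    return 1000.0 * dh / denom - 273.15


def duplex_free_energy(
    probe: str,
    target: str,
    params: DuplexParams = DEFAULT_PARAMS,
) -> float:
    """ΔG (kcal/mol) of ``probe`` annealed antiparallel to ``target``.

    ``probe`` and ``target`` are both written 5'->3' and must have equal
    length; position ``i`` of the probe pairs with position ``L-1-i`` of the
    target, so a perfect duplex has ``probe == reverse_complement(target)``.
    Mismatched positions knock out their adjacent stacks, each contributing
    ``params.mismatch_dg_penalty`` instead of the table value.
    """
    probe = _check_sequence(probe)
    target = _check_sequence(target)
    if len(probe) != len(target):
        raise AlignmentError(
            f"probe length {len(probe)} != target length {len(target)}"
        )
    table = params.table
    t_k = params.temperature_for_dg + 273.15
    rc_target = reverse_complement(target)
    match = [p == c for p, c in zip(probe, rc_target)]

    dh, ds, penalty = 0.0, 0.0, 0.0
    n_paired_stacks = 0
    for i in range(len(probe) - 1):
        if match[i] and match[i + 1]:
            h, s = table[probe[i : i + 2]]
            dh += h
            ds += s
            n_paired_stacks += 1
        else:
            penalty += params.mismatch_dg_penalty
    if match[0]:
        h, s = table[_init_key(probe[0])]
        dh += h
        ds += s
    if match[-1]:
        h, s = table[_init_key(probe[-1])]
        dh += h
        ds += s
    ds += 0.368 * n_paired_stacks * math.log(params.monovalent_salt)
    return dh - t_k * ds / 1000.0 + penalty


def duplex_energy(
    probe: str,
    target: str,
    params: DuplexParams = DEFAULT_PARAMS,
) -> DuplexEnergy:
    """Convenience bundle of ΔG (probe vs target) and Tm (of the probe)."""
    return DuplexEnergy(
        delta_g=duplex_free_energy(probe, target, params),
        tm=melting_temp(probe, params),
    )
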