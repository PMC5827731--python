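"""Charge-architecture metrics for protein sequences.

Intrinsically disordered regions (IDRs) of phase-separating proteins such as
nucleophosmin (NPM1) are polyampholytes: their behaviour is governed less by
overall composition than by how charge is arranged in blocks ("tracts") along
the chain.  This module quantifies that architecture with two complementary
measures:

* **NCPR** (net charge per residue): ``(count{K,R} - count{D,E}) / length``
  over a window or annotated tract.  Histidine is counted neutral, following
  the convention of sequence-patterning tools for IDRs.
* **pH-dependent net charge**: the Henderson–Hasselbalch sum over ionizable
  side chains and (optionally) the termini, for a configurable pKa set.

It also applies phosphomimetic substitutions (S/T -> D) so that the charge
consequences of e.g. mitotic CDK1 phosphorylation of the NPM1 B2-tract can be
computed directly on the sequence.

The bundled NPM1 fixture (UniProt P06748) and its default tract annotation
live in :mod:`phasekit.data` and are exposed via :func:`load_npm1` and
:func:`load_npm1_tracts`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO

__all__ = [
    "CANONICAL_AA",
    "ProteinSequence",
    "TractAnnotation",
    "PkaSet",
    "ChargeProfile",
    "PKA_PRESETS",
    "ncpr",
    "ncpr_profile",
    "net_charge_at_pH",
    "apply_phosphomimetic",
    "read_fasta",
    "load_tracts",
    "load_npm1",
    "load_npm1_tracts",
    "round_half_even",
]

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

_POSITIVE = frozenset("KR")  # H neutral in NCPR (patterning-tool convention)
_NEGATIVE = frozenset("DE")


def round_half_even(x: float, ndigits: int) -> float:
    """Banker's rounding to *ndigits*, used for all values quoted at printed precision."""
    return float(np.round(x, ndigits))


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with 1-based residue indexing."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        for i, aa in enumerate(self.residues, start=1):
            if aa not in CANONICAL_AA:
                raise ValueError(
                    f"sequence {self.id!r}: non-canonical residue {aa!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def window(self, start: int, end: int) -> str:
        """Residues *start..end*, 1-based inclusive."""
        if not (1 <= start <= end <= len(self.residues)):
            raise ValueError(
                f"window {start}-{end} outside sequence bounds 1-{len(self.residues)}"
            )
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class TractAnnotation:
    """A named sequence window (1-based inclusive) with a charge polarity label."""

    name: str
    start: int
    end: int
    polarity: str = "acidic"  # {acidic, basic, folded}

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"tract {self.name!r}: invalid bounds {self.start}-{self.end}")
        if self.polarity not in {"acidic", "basic", "folded"}:
            raise ValueError(f"tract {self.name!r}: unknown polarity {self.polarity!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


def validate_tract_set(tracts: Sequence[TractAnnotation], seq_length: int | None = None) -> None:
    """Check that tracts do not overlap (and fit the sequence, if a length is given)."""
    spans = sorted((t.start, t.end, t.name) for t in tracts)
    for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"tracts {n1!r} and {n2!r} overlap")
    if seq_length is not None:
        for t in tracts:
            if t.end > seq_length:
                raise ValueError(f"tract {t.name!r} extends past sequence length {seq_length}")


@dataclass(frozen=True)
class PkaSet:
    """Side-chain and terminal pKa values used for pH-dependent net charge.

    ``acidic`` groups contribute -1/(1+10^(pKa-pH)); ``basic`` groups
    +1/(1+10^(pH-pKa)).  Histidine belongs to the basic set here even though
    it is excluded from NCPR.
    """

    name: str
    acidic: Mapping[str, float]  # residue -> pKa, charge -1 when deprotonated
    basic: Mapping[str, float]  # residue -> pKa, charge +1 when protonated
    n_term: float
    c_term: float
    include_termini: bool = True

    def __post_init__(self) -> None:
        for pka in (*self.acidic.values(), *self.basic.values(), self.n_term, self.c_term):
            if not (0.0 < pka < 14.0):
                raise ValueError(f"pKa set {self.name!r}: pKa {pka} outside (0, 14)")


#: Named pKa presets.  "protcalc" mirrors the protein calculator the netcharge
#: figure of merit was anchored to; "emboss" mirrors the EMBOSS iep defaults.
PKA_PRESETS: dict[str, PkaSet] = {
    "protcalc": PkaSet(
        name="protcalc",
        acidic={"D": 4.0, "E": 4.4, "C": 8.5, "Y": 10.0},
        basic={"K": 10.0, "R": 12.0, "H": 6.5},
        n_term=8.0,
        c_term=3.1,
    ),
    "emboss": PkaSet(
        name="emboss",
        acidic={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
        basic={"K": 10.8, "R": 12.5, "H": 6.5},
        n_term=8.6,
        c_term=3.6,
    ),
}


@dataclass(frozen=True)
class ChargeProfile:
    """Sliding-window NCPR profile (full windows only, clipped windows excluded)."""

    window_size: int
    centers: np.ndarray = field(repr=False)  # 1-based window-center positions
    values: np.ndarray = field(repr=False)  # NCPR per window, in [-1, 1]

    def __post_init__(self) -> None:
        if np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise ValueError("NCPR profile contains values outside [-1, 1]")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def ncpr(seq: ProteinSequence, window: TractAnnotation | tuple[int, int] | None = None) -> float:
    """Net charge per residue of a window (default: the whole sequence).

    NCPR = (count{K,R} - count{D,E}) / window length, histidine neutral.
    """
    if window is None:
        sub = seq.residues
    elif isinstance(window, TractAnnotation):
        sub = seq.window(window.start, window.end)
    else:
        sub = seq.window(*window)
    pos = sum(1 for aa in sub if aa in _POSITIVE)
    neg = sum(1 for aa in sub if aa in _NEGATIVE)
    return (pos - neg) / len(sub)


def ncpr_profile(seq: ProteinSequence, window_size: int, step: int = 1) -> ChargeProfile:
    """Sliding-window NCPR along the sequence.

    Only full windows are evaluated; windows that would be clipped at either
    terminus are excluded.  Window centers are reported on the 1-based residue
    axis (mean of first and last residue index of the window).
    """
    n = len(seq)
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if window_size > n:
        raise ValueError(f"window_size {window_size} exceeds sequence length {n}")
    if step < 1:
        raise ValueError("step must be >= 1")
    charges = np.array(
        [1.0 if aa in _POSITIVE else -1.0 if aa in _NEGATIVE else 0.0 for aa in seq.residues]
    )
    csum = np.concatenate([[0.0], np.cumsum(charges)])
    starts = np.arange(0, n - window_size + 1, step)
    values = (csum[starts + window_size] - csum[starts]) / window_size
    centers = starts + (window_size + 1) / 2.0  # 1-based center
    return ChargeProfile(window_size=window_size, centers=centers, values=values)


def net_charge_at_pH(
    seq: ProteinSequence,
    pH: float,
    pka_set: PkaSet | str = "protcalc",
) -> float:
    """Henderson–Hasselbalch net charge (elementary charges) at the given pH.

    Acidic groups (D, E, C, Y, C-terminus) contribute -1/(1+10^(pKa-pH));
    basic groups (K, R, H, N-terminus) contribute +1/(1+10^(pH-pKa)).
    Termini are included when the pKa set's ``include_termini`` flag is set.
    """
    if not (0.0 < pH < 14.0):
        raise ValueError(f"pH {pH} outside (0, 14)")
    pka = PKA_PRESETS[pka_set] if isinstance(pka_set, str) else pka_set
    q = 0.0
    for aa in seq.residues:
        if aa in pka.acidic:
            q -= 1.0 / (1.0 + 10.0 ** (pka.acidic[aa] - pH))
        elif aa in pka.basic:
            q += 1.0 / (1.0 + 10.0 ** (pH - pka.basic[aa]))
    if pka.include_termini:
        q += 1.0 / (1.0 + 10.0 ** (pH - pka.n_term))
        q -= 1.0 / (1.0 + 10.0 ** (pka.c_term - pH))
    return q


def apply_phosphomimetic(seq: ProteinSequence, positions: Iterable[int]) -> ProteinSequence:
    """Replace S/T at the given 1-based positions with D (phosphomimetic).

    Returns a new sequence; the input is untouched.  Positions must hold Ser
    or Thr — phosphomimetic substitution of any other residue is rejected.
    """
    residues = list(seq.residues)
    positions = list(positions)
    for p in positions:
        if not (1 <= p <= len(residues)):
            raise ValueError(f"position {p} outside sequence bounds 1-{len(residues)}")
        if residues[p - 1] not in ("S", "T"):
            raise ValueError(
                f"position {p} holds {residues[p - 1]!r}, not S/T; cannot phosphomimic"
            )
    for p in positions:
        residues[p - 1] = "D"
    suffix = "" if not positions else "_phosphomimetic"
    return replace(seq, id=seq.id + suffix, residues="".join(residues))


# ---------------------------------------------------------------------------
# I/O and bundled fixtures
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read all records of a FASTA file as :class:`ProteinSequence`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [ProteinSequence(id=r.id, residues=str(r.seq).upper()) for r in records]


def write_fasta(seqs: Sequence[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


def load_tracts(path: str | Path) -> list[TractAnnotation]:
    """Load tract annotations from a YAML sidecar (``tracts:`` list of name/start/end/polarity)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["tracts"] if isinstance(doc, dict) else doc
    tracts = [
        TractAnnotation(
            name=str(e["name"]), start=int(e["start"]), end=int(e["end"]),
            polarity=str(e.get("polarity", "acidic")),
        )
        for e in entries
    ]
    validate_tract_set(tracts)
    return tracts


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("phasekit").joinpath("data", name)))


def load_npm1() -> ProteinSequence:
    """The bundled human NPM1 sequence (UniProt P06748, 294 residues)."""
    return read_fasta(_data_path("npm1_p06748.fasta"))[0]


def load_npm1_tracts() -> dict:
    """Bundled NPM1 annotation: tracts, CDK1 phosphosites, and construct windows."""
    with open(_data_path("npm1_tracts.yaml")) as fh:
        doc = yaml.safe_load(fh)
    tracts = [
        TractAnnotation(name=e["name"], start=e["start"], end=e["end"], polarity=e["polarity"])
        for e in doc["tracts"]
    ]
    validate_tract_set(tracts)
    return {
        "tracts": {t.name: t for t in tracts},
        "phosphosites": list(doc["phosphosites"]),
        "constructs": {k: (v["start"], v["end"]) for k, v in doc["constructs"].items()},
    }
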