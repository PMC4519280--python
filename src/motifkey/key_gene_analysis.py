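"""Gene-to-motif mapping and the FN/FTN/FT over-representation parameters.

For a motif class with instance set I and size k, every instance contributes
each of its k member genes once, so with ``freq(g)`` = number of instances
containing gene ``g``:

    FN  = number of distinct genes appearing in the class,
    FTN = sum of freq(g) over those genes = k * |I|,
    FT  = FN / FTN  in (0, 1].

A *low* FT marks a class whose few genes recur across many instances —
the class is carried by a small recurrent gene set. The pipeline selects
the minimal-FT class among significant classes and ranks its genes by
frequency to nominate key regulators. The module also carries the
transcription-factor importance product (occurrence frequency x weight).
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd

from .graph_model import MotifID


def round_half_away(value: float, ndigits: int = 3) -> float:
    """Round half away from zero (0.5625 -> 0.563), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class KeyGeneRecord:
    """FN/FTN/FT and per-gene frequencies for one motif class."""

    motif: MotifID
    gene_freq: dict = field(default_factory=dict)
    fn: int = 0
    ftn: int = 0

    def __post_init__(self):
        if self.gene_freq and not (self.fn or self.ftn):
            self.fn = len(self.gene_freq)
            self.ftn = sum(self.gene_freq.values())
        if self.ftn <= 0 or self.fn <= 0:
            raise ValueError("FN and FTN must be positive")
        if self.fn > self.ftn:
            raise ValueError(f"FN={self.fn} cannot exceed FTN={self.ftn}")

    @property
    def ft(self) -> float:
        """FN/FTN at full precision."""
        return self.fn / self.ftn

    @property
    def ft_display(self) -> float:
        """FT rounded half-away-from-zero to 3 decimals (report convention)."""
        return round_half_away(self.ft, 3)

    @property
    def n_instances(self) -> Optional[int]:
        if not self.gene_freq:
            return None
        return self.ftn // self.motif.k


def gene_frequencies(instances) -> Counter:
    """Per-gene instance counts for one motif class.

    ``freq(g)`` = number of instances whose member tuple contains ``g``.
    All instances must share one class.
    """
    if not instances:
        return Counter()
    motif = instances[0].motif
    freq: Counter = Counter()
    for inst in instances:
        if inst.motif != motif:
            raise ValueError(
                f"mixed motif classes: {inst.motif.bits} != {motif.bits}"
            )
        freq.update(set(inst.members))
    return freq


def compute_key_gene_record(instances) -> KeyGeneRecord:
    """FN, FTN and FT for a non-empty single-class instance list."""
    if not instances:
        raise ValueError("cannot compute a key-gene record from no instances")
    freq = gene_frequencies(instances)
    return KeyGeneRecord(motif=instances[0].motif, gene_freq=dict(freq))


def select_key_motif(records) -> KeyGeneRecord:
    """The record with minimal FT; ties go to the larger FTN, then to the
    lexicographically smaller motif bitstring (deterministic)."""
    records = list(records)
    if not records:
        raise ValueError("no key-gene records to select from")
    return min(records, key=lambda r: (r.ft, -r.ftn, r.motif.bits))


def rank_key_genes(record: KeyGeneRecord, top: int = 10) -> list:
    """Top genes of a class by descending frequency, ties alphabetical.

    Returns (gene, frequency) pairs, truncated to ``top``.
    """
    if top < 1:
        raise ValueError("top must be >= 1")
    ranked = sorted(record.gene_freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top]


def tf_importance(frequency: float, weight: float) -> float:
    """Transcription-factor importance = occurrence frequency x weight."""
    if not 0.0 <= frequency <= 1.0:
        raise ValueError(f"TF frequency {frequency} outside [0, 1]")
    if weight < 0.0:
        raise ValueError(f"TF weight {weight} must be >= 0")
    return frequency * weight


@dataclass
class TFRecord:
    """A transcription factor with occurrence frequency, weight and importance."""

    name: str
    frequency: float
    weight: float

    @property
    def importance(self) -> float:
        return tf_importance(self.frequency, self.weight)


# ---------------------------------------------------------------------------
# Packaged reference table (56 motif classes with published FN/FTN/FT)
# ---------------------------------------------------------------------------

def load_reference_table() -> pd.DataFrame:
    """The packaged 56-row reference table of published motif-class
    parameters: columns motif_id, label, FTN, FN, FT (FT as printed,
    3-decimal display)."""
    ref = importlib.resources.files("motifkey").joinpath("data/table1.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"motif_id": str, "label": str})
    return df


def replay_reference_table() -> pd.DataFrame:
    """Recompute FT = FN/FTN for every reference row.

    Adds ``ft_recomputed`` (3-decimal half-away-from-zero display value) and
    ``matches`` (recomputed display value equals the published FT) columns.
    Every motif_id is validated as a well-formed, weakly connected motif.
    """
    df = load_reference_table()
    recs = []
    for row in df.itertuples(index=False):
        motif = MotifID.from_bits(row.motif_id)  # validates the bitstring
        rec = KeyGeneRecord(motif=motif, fn=int(row.FN), ftn=int(row.FTN))
        recs.append(rec)
    df = df.copy()
    df["ft_recomputed"] = [r.ft_display for r in recs]
    df["matches"] = [
        rec.ft_display == float(printed) for rec, printed in zip(recs, df["FT"])
    ]
    return df


def reference_records() -> list:
    """The reference table as :class:`KeyGeneRecord` objects (no gene maps)."""
    df = load_reference_table()
    return [
        KeyGeneRecord(
            motif=MotifID.from_bits(row.motif_id), fn=int(row.FN), ftn=int(row.FTN)
        )
        for row in df.itertuples(index=False)
    ]


def key_gene_report_tsv(records) -> str:
    """TSV report: motif_id, k, instances, FN, FTN, FT (3dp), then
    gene:frequency pairs in rank order."""
    lines = ["motif_id\tk\tinstances\tFN\tFTN\tFT\tgene_frequencies"]
    for r in records:
        genes = ";".join(
            f"{g}:{c}" for g, c in rank_key_genes(r, top=max(1, len(r.gene_freq)))
        ) if r.gene_freq else ""
        n_inst = r.n_instances if r.n_instances is not None else ""
        lines.append(
            f"{r.motif.bits}\t{r.motif.k}\t{n_inst}\t{r.fn}\t{r.ftn}\t"
            f"{r.ft_display:.3f}\t{genes}"
        )
    return "\n".join(lines) + "\n"
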