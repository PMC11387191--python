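"""Sequence-context features of stop codons.

Each variant is a stop-anchored nucleotide context: a stretch of spliced
mRNA with a stop codon (TAA/TAG/TGA) at a known offset. Readthrough
efficiency depends strongly on this local context, so every variant is
encoded into a fixed set of features:

* the stop codon type (reported in RNA form: UAA/UAG/UGA),
* the identity of the nucleotides up to eight positions downstream
  (``down_1`` .. ``down_8``, the first base after the stop triplet) and
  upstream (``up_1`` .. ``up_8``, the base immediately 5' of the stop),
* the in-frame codon immediately upstream of the stop, the amino acid it
  encodes and whether it ends in A,
* G+C content of the whole context,
* mean codon adaptation index (CAI) and tRNA adaptation index (tAI) over
  all in-frame codons upstream of the stop, given user-supplied
  codon->weight tables.

Positions that fall outside the available sequence are encoded with the
explicit "absent" level ``-`` rather than dropped, so short contexts near
transcript ends remain usable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqIO import parse as fasta_parse

STOP_CODONS = ("TAA", "TAG", "TGA")
NUCLEOTIDES = ("A", "C", "G", "T")
#: level used for positional features beyond the available sequence
ABSENT = "-"
FLANK_POSITIONS = 8

_VALID_SEQ = re.compile(r"^[ACGT]+$")

# standard genetic code; stops encoded as '*'
GENETIC_CODE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    GENETIC_CODE[_stop] = "*"


@dataclass
class VariantContext:
    """A stop-anchored sequence context.

    Parameters
    ----------
    variant_id : str
        Unique identifier.
    sequence : str
        DNA sequence (A/C/G/T only).
    stop_offset : int
        0-based index of the first base of the stop codon (72 for the
        standard 147-nt premature-stop contexts, 66 for the 135-nt
        natural-stop contexts).
    is_control : bool
        Marks the no-nonsense control variant, which carries a sense
        codon at ``stop_offset`` and defines 100% readthrough.
    """

    variant_id: str
    sequence: str
    stop_offset: int
    is_control: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        match = _VALID_SEQ.match(self.sequence)
        if not match:
            bad = next(
                i for i, c in enumerate(self.sequence) if c not in "ACGT"
            )
            raise ValueError(
                f"{self.variant_id}: non-ACGT character "
                f"{self.sequence[bad]!r} at position {bad}"
            )
        if self.stop_offset < 0 or len(self.sequence) < self.stop_offset + 3:
            raise ValueError(
                f"{self.variant_id}: sequence too short for stop_offset="
                f"{self.stop_offset}"
            )
        if not self.is_control and self.stop_codon not in STOP_CODONS:
            raise ValueError(
                f"{self.variant_id}: triplet {self.stop_codon!r} at offset "
                f"{self.stop_offset} is not a stop codon"
            )

    @property
    def stop_codon(self) -> str:
        return self.sequence[self.stop_offset : self.stop_offset + 3]

    @property
    def upstream(self) -> str:
        return self.sequence[: self.stop_offset]

    @property
    def downstream(self) -> str:
        return self.sequence[self.stop_offset + 3 :]


def load_weight_table(path) -> dict[str, float]:
    """Read a two-column codon -> weight TSV into a dict."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (codon, weight)")
    return dict(
        zip(table.iloc[:, 0].str.upper(), table.iloc[:, 1].astype(float))
    )


def _mean_codon_weight(codons: list[str], table: dict[str, float]) -> float:
    if not codons:
        raise ValueError("empty codon list")
    weights = []
    for codon in codons:
        if codon not in table:
            raise KeyError(f"codon {codon!r} not in weight table")
        weights.append(table[codon])
    return float(np.mean(weights))


def cai(codons: list[str], cai_table: dict[str, float]) -> float:
    """Mean CAI weight across codons (arithmetic mean)."""
    return _mean_codon_weight(codons, cai_table)


def tai(codons: list[str], tai_table: dict[str, float]) -> float:
    """Mean tAI weight across codons (arithmetic mean)."""
    return _mean_codon_weight(codons, tai_table)


def upstream_codons(ctx: VariantContext) -> list[str]:
    """In-frame codons upstream of the stop, anchored at the stop.

    Codons are read in steps of three walking back from the stop, so they
    coincide with translation-frame codons whenever the upstream sequence
    is in frame with the stop.
    """
    n_codons = ctx.stop_offset // 3
    start = ctx.stop_offset - 3 * n_codons
    return [
        ctx.sequence[i : i + 3]
        for i in range(start, ctx.stop_offset, 3)
    ]


def extract_features(
    ctx: VariantContext,
    cai_table: dict[str, float] | None = None,
    tai_table: dict[str, float] | None = None,
) -> dict:
    """Encode one context into its feature record (as a plain dict)."""
    seq = ctx.sequence
    off = ctx.stop_offset
    stop = ctx.stop_codon
    record: dict = {
        "variant_id": ctx.variant_id,
        "is_control": ctx.is_control,
        "stop_type": stop.replace("T", "U") if stop in STOP_CODONS else ABSENT,
    }
    down = ctx.downstream
    up = ctx.upstream
    for k in range(1, FLANK_POSITIONS + 1):
        record[f"down_{k}"] = down[k - 1] if len(down) >= k else ABSENT
        record[f"up_{k}"] = up[off - k] if off >= k else ABSENT
    up_codon = seq[off - 3 : off] if off >= 3 else ABSENT
    record["up_codon"] = up_codon
    record["up_aa"] = GENETIC_CODE.get(up_codon, ABSENT)
    record["up_codon_ends_A"] = up_codon != ABSENT and up_codon[2] == "A"
    record["gc_content"] = (seq.count("G") + seq.count("C")) / len(seq)
    codons = upstream_codons(ctx)
    record["cai_up"] = (
        cai(codons, cai_table) if cai_table is not None and codons else np.nan
    )
    record["tai_up"] = (
        tai(codons, tai_table) if tai_table is not None and codons else np.nan
    )
    return record


def features_table(
    contexts: list[VariantContext],
    cai_table: dict[str, float] | None = None,
    tai_table: dict[str, float] | None = None,
    include_controls: bool = True,
) -> pd.DataFrame:
    """Feature records for many contexts, indexed by variant_id."""
    records = [
        extract_features(c, cai_table, tai_table)
        for c in contexts
        if include_controls or not c.is_control
    ]
    table = pd.DataFrame.from_records(records).set_index("variant_id")
    return table


# ---------------------------------------------------------------------------
# context I/O


def read_contexts_fasta(
    path, stop_offset: int = 72, control_ids: set[str] | None = None
) -> list[VariantContext]:
    """Read contexts from FASTA; one stop offset for all records."""
    control_ids = control_ids or set()
    return [
        VariantContext(
            rec.id, str(rec.seq), stop_offset, is_control=rec.id in control_ids
        )
        for rec in fasta_parse(path, "fasta")
    ]


def read_contexts_tsv(path) -> list[VariantContext]:
    """Read contexts from TSV with columns variant_id, sequence,
    stop_offset and optional is_control."""
    table = pd.read_csv(path, sep="\t")
    has_control = "is_control" in table.columns
    return [
        VariantContext(
            str(row.variant_id),
            row.sequence,
            int(row.stop_offset),
            is_control=bool(row.is_control) if has_control else False,
        )
        for row in table.itertuples()
    ]


def write_contexts_tsv(contexts: list[VariantContext], path) -> None:
    pd.DataFrame(
        {
            "variant_id": [c.variant_id for c in contexts],
            "sequence": [c.sequence for c in contexts],
            "stop_offset": [c.stop_offset for c in contexts],
            "is_control": [c.is_control for c in contexts],
        }
    ).to_csv(path, sep="\t", index=False)
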