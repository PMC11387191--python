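"""In-silico nonsense saturation mutagenesis of transcripts.

For every sense codon of a coding sequence, one to three nucleotide
substitutions can convert it into each of the three stop codons. This
module enumerates all such stop gains, builds the surrounding sequence
context for each (72 nt of spliced sequence either side by default,
trimmed near transcript ends), predicts per-drug readthrough with fitted
sequence-context models and summarises which drug is predicted to work
best and how many variants clear clinically motivated readthrough
thresholds.

Enumeration streams one codon at a time so genome-scale scans stay within
bounded memory; predictions are made in batches per transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO import parse as fasta_parse

from .features import STOP_CODONS, VariantContext, features_table

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0)


@dataclass
class TranscriptRecord:
    """A spliced transcript with CDS coordinates (1-based inclusive)."""

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        cds = self.cds
        if len(cds) % 3:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(cds)} not divisible by 3"
            )
        if cds[-3:] not in STOP_CODONS:
            raise ValueError(
                f"{self.transcript_id}: CDS does not end in a stop codon"
            )
        internal = [
            i // 3 + 1
            for i in range(0, len(cds) - 3, 3)
            if cds[i : i + 3] in STOP_CODONS
        ]
        if internal:
            raise ValueError(
                f"{self.transcript_id}: internal in-frame stop at codon(s) "
                f"{internal[:3]}"
            )

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start - 1 : self.cds_end]

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class StopGain:
    """One enumerated stop-gain variant (prediction not yet attached)."""

    transcript_id: str
    codon_index: int  # 1-based over sense codons (the natural stop excluded)
    stop_type: str  # RNA form, e.g. "UGA"
    n_substitutions: int
    context: VariantContext


def enumerate_stop_gains(
    transcript: TranscriptRecord, flank: int = 72
) -> Iterator[StopGain]:
    """Yield every stop gain of a transcript.

    Each sense codon (the natural termination codon is excluded) is
    replaced by each stop type at Hamming distance >= 1, giving exactly
    ``3 * (L - 1)`` variants for an L-codon CDS. The emitted context is
    the spliced sequence around the introduced stop, trimmed to ``flank``
    nucleotides each side (shorter near transcript ends, with the stop
    offset adjusted accordingly).
    """
    seq = transcript.sequence
    cds0 = transcript.cds_start - 1
    for codon_index in range(1, transcript.n_codons):
        pos = cds0 + 3 * (codon_index - 1)
        codon = seq[pos : pos + 3]
        if any(c not in "ACGT" for c in codon):
            logger.warning(
                "%s codon %d contains non-ACGT base; skipped",
                transcript.transcript_id,
                codon_index,
            )
            continue
        if codon in STOP_CODONS:
            # pre-existing stop: mutating one stop into another is not a gain
            continue
        for stop in STOP_CODONS:
            distance = _hamming(codon, stop)
            if distance == 0:
                continue
            start = max(0, pos - flank)
            end = min(len(seq), pos + 3 + flank)
            context_seq = (
                seq[start:pos] + stop + seq[pos + 3 : end]
            )
            ctx = VariantContext(
                f"{transcript.transcript_id}_c{codon_index}_{stop}",
                context_seq,
                stop_offset=pos - start,
            )
            yield StopGain(
                transcript_id=transcript.transcript_id,
                codon_index=codon_index,
                stop_type=stop.replace("T", "U"),
                n_substitutions=distance,
                context=ctx,
            )


def predict_saturation(
    transcripts: Iterable[TranscriptRecord],
    fits: dict[str, "ReadthroughResults"],
    flank: int = 72,
    cai_table=None,
    tai_table=None,
) -> pd.DataFrame:
    """Per-drug readthrough predictions for every stop gain.

    One row per transcript/codon/stop-type with columns ``rtp_<drug>``,
    the best drug (argmax of predicted readthrough, ties broken by drug
    name order and logged) and its predicted value.
    """
    drugs = sorted(fits)
    frames = []
    for transcript in transcripts:
        stubs = list(enumerate_stop_gains(transcript, flank=flank))
        if not stubs:
            continue
        feats = features_table(
            [s.context for s in stubs], cai_table, tai_table
        )
        frame = pd.DataFrame(
            {
                "transcript_id": [s.transcript_id for s in stubs],
                "codon_index": [s.codon_index for s in stubs],
                "stop_type": [s.stop_type for s in stubs],
                "n_substitutions": [s.n_substitutions for s in stubs],
                "context": [s.context.sequence for s in stubs],
                "stop_offset": [s.context.stop_offset for s in stubs],
            },
            index=feats.index,
        )
        for drug in drugs:
            frame[f"rtp_{drug}"] = fits[drug].predict(feats)
        frames.append(frame)
    predictions = pd.concat(frames, ignore_index=True)
    rtp_cols = [f"rtp_{d}" for d in drugs]
    rtp = predictions[rtp_cols].to_numpy()
    best_idx = rtp.argmax(axis=1)  # argmax takes the first of tied maxima
    ties = (rtp == rtp.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info(
            "best-drug ties at %d variant(s); broken by drug name order",
            int(ties.sum()),
        )
    predictions["best_drug"] = [drugs[i] for i in best_idx]
    predictions["best_rtp"] = rtp.max(axis=1)
    return predictions


def summarize_thresholds(
    predictions: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Fraction of variants above each readthrough threshold.

    One row per drug plus an ``all_drugs`` row that uses the best drug
    per variant.
    """
    if predictions.empty:
        raise ValueError("empty prediction table")
    rtp_cols = [c for c in predictions.columns if c.startswith("rtp_")]
    rows = {}
    for col in rtp_cols + ["best_rtp"]:
        name = "all_drugs" if col == "best_rtp" else col[len("rtp_"):]
        values = predictions[col].to_numpy()
        rows[name] = {
            thr: float((values > thr).mean()) for thr in thresholds
        }
    return pd.DataFrame(rows).T


def best_drug_share(predictions: pd.DataFrame) -> pd.Series:
    """Share of variants for which each drug is predicted optimal."""
    share = predictions["best_drug"].value_counts(normalize=True)
    return share.sort_index()


def to_bedgraph(
    predictions: pd.DataFrame, transcript: TranscriptRecord, drug: str, path
) -> None:
    """Write per-codon predictions as a transcript-coordinate bedGraph
    (0-based half-open intervals covering each codon; one stop type per
    position keeps the track single-valued, so the best stop is used)."""
    sub = predictions[
        predictions["transcript_id"] == transcript.transcript_id
    ]
    col = f"rtp_{drug}"
    best = sub.groupby("codon_index")[col].max()
    cds0 = transcript.cds_start - 1
    with open(path, "w") as handle:
        handle.write(
            f'track type=bedGraph name="{transcript.transcript_id}_{drug}"\n'
        )
        for codon_index, value in best.items():
            start = cds0 + 3 * (codon_index - 1)
            handle.write(
                f"{transcript.transcript_id}\t{start}\t{start + 3}\t"
                f"{value:.4f}\n"
            )


def read_transcripts(
    fasta_path, cds_path
) -> list[TranscriptRecord]:
    """Load transcripts from FASTA plus a transcript_id/cds_start/cds_end
    TSV (1-based inclusive coordinates)."""
    cds = pd.read_csv(cds_path, sep="\t").set_index("transcript_id")
    records = []
    for rec in fasta_parse(fasta_path, "fasta"):
        if rec.id not in cds.index:
            logger.warning("no CDS coordinates for %s; skipped", rec.id)
            continue
        row = cds.loc[rec.id]
        records.append(
            TranscriptRecord(
                rec.id, str(rec.seq), int(row.cds_start), int(row.cds_end)
            )
        )
    return records
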