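"""Natural termination codon (NTC) contexts and PTC/NTC comparison.

Readthrough of a gene's own stop codon is what makes nonsense
suppression potentially toxic. To measure the contribution of local
sequence context to NTC readthrough without the confound of tandem 3'-UTR
stops, NTC contexts keep 66 nt upstream and 66 nt of 3' UTR around the
stop but substitute away every in-frame UTR stop codon with a 1-Hamming
edit (default map TAA->TAC, TAG->TGG, TGA->TGG). The distance (in codons)
from the NTC to the nearest *original* in-frame UTR stop is recorded: a
variant whose endogenous transcript has a proximal tandem stop can be
assumed readthrough-insensitive (readthrough over two stops is ~0), which
the tandem-threshold operation applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import STOP_CODONS

logger = logging.getLogger(__name__)

#: 1-Hamming substitutions removing in-frame UTR stops. The TAG->TGG and
#: TGA->TGG edits are both single-base and keep the grouping of the two
#: G-containing stops; the map is configurable.
DEFAULT_SUBSTITUTION_MAP = {"TAA": "TAC", "TAG": "TGG", "TGA": "TGG"}

UP_FLANK = 66
DOWN_FLANK = 66


@dataclass
class NTCContext:
    """A natural-stop context with tandem UTR stops removed.

    ``utr_stop_distance`` is the distance in codons from the NTC to the
    nearest original in-frame 3'-UTR stop (first UTR codon = 1); None if
    no stop fell within the retained window.
    """

    gene_id: str
    sequence: str
    ntc_offset: int
    utr_stop_distance: int | None
    trimmed: bool = False


def _validate_substitution_map(substitution_map: dict[str, str]) -> None:
    for stop, repl in substitution_map.items():
        if stop not in STOP_CODONS:
            raise ValueError(f"substitution key {stop!r} is not a stop codon")
        if repl in STOP_CODONS:
            raise ValueError(
                f"substitution {stop}->{repl} maps to another stop codon"
            )
        if len(repl) != 3 or sum(a != b for a, b in zip(stop, repl)) != 1:
            raise ValueError(
                f"substitution {stop}->{repl} is not a 1-Hamming edit"
            )


def build_ntc_context(
    gene_id: str,
    sequence: str,
    ntc_offset: int,
    substitution_map: dict[str, str] | None = None,
    up_flank: int = UP_FLANK,
    down_flank: int = DOWN_FLANK,
) -> NTCContext:
    """Build the NTC context of one transcript.

    Parameters
    ----------
    sequence : str
        Spliced transcript (or tail) containing the NTC and its 3' UTR.
    ntc_offset : int
        0-based index of the NTC's first base within ``sequence``.

    The context keeps ``up_flank`` nt upstream and ``down_flank`` nt of
    UTR (trimmed and flagged when the transcript is shorter) and replaces
    every in-frame UTR stop via ``substitution_map``.
    """
    substitution_map = substitution_map or DEFAULT_SUBSTITUTION_MAP
    _validate_substitution_map(substitution_map)
    sequence = sequence.upper()
    ntc = sequence[ntc_offset : ntc_offset + 3]
    if ntc not in STOP_CODONS:
        raise ValueError(
            f"{gene_id}: triplet {ntc!r} at offset {ntc_offset} is not a stop"
        )
    start = max(0, ntc_offset - up_flank)
    end = min(len(sequence), ntc_offset + 3 + down_flank)
    trimmed = (ntc_offset - start) < up_flank or (
        end - ntc_offset - 3
    ) < down_flank
    if trimmed:
        logger.info("%s: context trimmed to %d nt", gene_id, end - start)
    context = list(sequence[start:end])
    offset = ntc_offset - start
    distance = None
    utr_start = offset + 3
    for k, i in enumerate(range(utr_start, len(context) - 2, 3)):
        codon = "".join(context[i : i + 3])
        if codon in STOP_CODONS:
            context[i : i + 3] = list(substitution_map[codon])
            if distance is None:
                distance = k + 1
    return NTCContext(
        gene_id=gene_id,
        sequence="".join(context),
        ntc_offset=offset,
        utr_stop_distance=distance,
        trimmed=trimmed,
    )


def contexts_to_frame(contexts: list[NTCContext]) -> pd.DataFrame:
    """Tabular view (gene_id index) incl. the tandem-stop distances."""
    return pd.DataFrame(
        {
            "sequence": [c.sequence for c in contexts],
            "ntc_offset": [c.ntc_offset for c in contexts],
            "utr_stop_distance": [c.utr_stop_distance for c in contexts],
            "trimmed": [c.trimmed for c in contexts],
        },
        index=pd.Index([c.gene_id for c in contexts], name="gene_id"),
    )


def apply_tandem_threshold(
    readthrough: pd.DataFrame,
    distances: pd.Series,
    threshold_codons: int,
    rtp_col: str = "rtp",
) -> pd.DataFrame:
    """Zero the readthrough of variants with a proximal tandem stop.

    Variants whose original transcript had an in-frame 3'-UTR stop closer
    than ``threshold_codons`` codons are assumed to have 0% readthrough
    (readthrough would have to cross both stops); a threshold of 0 leaves
    the table unchanged. Idempotent, and pointwise non-increasing in the
    threshold.
    """
    adjusted = readthrough.copy()
    dist = distances.reindex(adjusted.index)
    zero = dist.notna() & (dist < threshold_codons)
    adjusted.loc[zero, rtp_col] = 0.0
    return adjusted


def compare_ptc_ntc(
    ptc: pd.DataFrame,
    ntc: pd.DataFrame,
    condition_col: str = "condition",
    rtp_col: str = "rtp",
    min_group: int = 20,
) -> pd.DataFrame:
    """Per-drug PTC vs NTC readthrough comparison.

    Reports the ratio of medians (PTC over NTC) and a two-sided Wilcoxon
    rank-sum p value, Benjamini-Hochberg adjusted across drugs. Groups
    with a zero NTC median get an undefined ratio (NaN, flagged).
    """
    drugs = sorted(
        set(ptc[condition_col].unique()) & set(ntc[condition_col].unique())
    )
    records = []
    for drug in drugs:
        a = ptc.loc[ptc[condition_col] == drug, rtp_col].dropna()
        b = ntc.loc[ntc[condition_col] == drug, rtp_col].dropna()
        if len(a) < min_group or len(b) < min_group:
            raise ValueError(
                f"{drug}: needs >= {min_group} values per group "
                f"(got {len(a)} PTC, {len(b)} NTC)"
            )
        median_ntc = float(b.median())
        ratio = float(a.median()) / median_ntc if median_ntc != 0 else np.nan
        if median_ntc == 0:
            logger.warning("%s: NTC median is 0; ratio undefined", drug)
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        records.append(
            {
                "condition": drug,
                "n_ptc": len(a),
                "n_ntc": len(b),
                "median_ptc": float(a.median()),
                "median_ntc": median_ntc,
                "median_ratio": ratio,
                "p": float(p),
            }
        )
    table = pd.DataFrame(records).set_index("condition")
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table
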