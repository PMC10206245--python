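"""Canonical miRNA seed-site scanning and TargetScan table ingestion.

Canonical site classes on a target UTR (TargetScan convention, Watson-Crick
only, no G:U wobble in the seed):

* seed = miRNA nucleotides 2-7 (5'->3'); a seed match in the UTR is the
  reverse complement of the seed;
* ``6mer``     seed match alone;
* ``7mer-m8``  seed match plus a Watson-Crick match to miRNA nucleotide 8
  at the adjacent 5' target position;
* ``7mer-A1``  seed match plus an 'A' at the target position opposite
  miRNA nucleotide 1 (the A is required regardless of the miRNA's nt 1);
* ``8mer``     both extensions.

Coordinates are 1-based inclusive on the provided UTR strand; each seed
locus is reported once under its best class
(8mer > 7mer-m8 > 7mer-A1 > 6mer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _normalize(seq: str, what: str) -> str:
    """Uppercase, T->U; reject non-nucleotide characters."""
    s = seq.upper().replace("T", "U")
    bad = sorted(set(s) - set("ACGU"))
    if bad:
        raise ValueError(f"invalid characters in {what}: {bad}")
    return s


def reverse_complement(seq: str) -> str:
    s = _normalize(seq, "sequence")
    return "".join(_COMPLEMENT[c] for c in reversed(s))


@dataclass(frozen=True)
class SeedSiteHit:
    mirna_id: str
    transcript_id: str
    site_type: str
    utr_start: int  # 1-based inclusive, 5'-most nucleotide of the site
    utr_end: int  # 1-based inclusive


def scan_seed_sites(
    mirna_seq: str,
    utr_seq: str,
    mirna_id: str = "miRNA",
    transcript_id: str = "transcript",
) -> list[SeedSiteHit]:
    """Find all canonical seed sites of one miRNA in one UTR.

    Returns hits ordered by position; overlapping seed loci are each
    reported, but a single locus appears once, under its best class.
    """
    mir = _normalize(mirna_seq, "miRNA")
    utr = _normalize(utr_seq, "UTR")
    if len(mir) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    if not utr:
        raise ValueError("empty UTR")

    seed_rc = "".join(_COMPLEMENT[c] for c in reversed(mir[1:7]))
    m8_target = _COMPLEMENT[mir[7]]  # WC partner of miRNA nt 8

    hits: list[SeedSiteHit] = []
    k = utr.find(seed_rc)
    while k != -1:
        has_m8 = k >= 1 and utr[k - 1] == m8_target
        has_a1 = k + 6 < len(utr) and utr[k + 6] == "A"
        if has_m8 and has_a1:
            site, start, end = "8mer", k, k + 7
        elif has_m8:
            site, start, end = "7mer-m8", k, k + 6
        elif has_a1:
            site, start, end = "7mer-A1", k + 1, k + 7
        else:
            site, start, end = "6mer", k + 1, k + 6
        hits.append(SeedSiteHit(mirna_id, transcript_id, site, start, end))
        k = utr.find(seed_rc, k + 1)
    return hits


@dataclass(frozen=True)
class TargetPrediction:
    mirna_id: str
    gene_id: str
    cumulative_context_score: float


def load_targetscan(
    path: str | Path,
    score_threshold: float = -0.4,
    mirna_col: str = "miRNA",
    gene_col: str = "gene",
    score_col: str = "context_score",
    species: str | None = None,
    species_col: str = "species",
) -> list[TargetPrediction]:
    """Load a TargetScan-style table, keeping rows with score <= threshold.

    The cumulative weighted context++ score is TargetScan's gene-level
    predicted targeting efficacy; more negative = stronger predicted
    repression, so the filter is a one-sided "at most" cut.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in (mirna_col, gene_col, score_col) if c not in df.columns]
    if missing:
        raise ValueError(f"TargetScan table missing column(s): {missing}")
    if species is not None and species_col in df.columns:
        df = df[df[species_col] == species]
    preds: list[TargetPrediction] = []
    for _, row in df.iterrows():
        try:
            score = float(row[score_col])
        except (TypeError, ValueError):
            logger.warning(
                "skipping row with unparseable score: %s/%s=%r",
                row[mirna_col],
                row[gene_col],
                row[score_col],
            )
            continue
        if score <= score_threshold:
            preds.append(TargetPrediction(row[mirna_col], row[gene_col], score))
    return preds


def intersect_expressed(
    predictions: list[TargetPrediction], expressed_genes
) -> list[TargetPrediction]:
    """Predictions whose gene is in the expressed set, ordered (miRNA, gene)."""
    expressed = set(expressed_genes)
    kept = {
        (p.mirna_id, p.gene_id): p for p in predictions if p.gene_id in expressed
    }
    return [kept[k] for k in sorted(kept)]
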