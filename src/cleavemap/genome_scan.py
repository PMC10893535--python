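"""Motif prevalence scanning over coding sequences.

Counts (possibly overlapping) motif occurrences on the sense strand of each
CDS — MazF-family toxins cleave single-stranded transcripts, so only the
mRNA-sense orientation matters — and attaches a zeroth-order composition
expectation: with per-CDS base frequencies f, a random position matches with
probability p = prod_j f(motif_j), the expected count over L - m + 1 windows
is (L - m + 1) p, and the upper-tail Poisson probability of the observed
count serves as an enrichment statistic.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, replace

import pandas as pd
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

_LOCUS_RE = re.compile(r"\[locus_tag=([^\]\s]+)\]")
_PRODUCT_RE = re.compile(r"\[protein=([^\]]+)\]")


@dataclass(frozen=True)
class GeneHit:
    """Motif occurrences in one CDS with a composition-based expectation."""

    locus_tag: str
    cds_length: int
    occurrence_count: int
    expected_count: float | None = None
    p_value: float | None = None
    q_value: float | None = None
    product: str | None = None


def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _parse_header(header: str) -> tuple[str, str | None]:
    m = _LOCUS_RE.search(header)
    locus = m.group(1) if m else header.split()[0]
    pm = _PRODUCT_RE.search(header)
    return locus, (pm.group(1) if pm else None)


def count_occurrences(sequence: str, motif: str) -> int:
    """Overlapping sense-strand motif matches (T and U equivalent)."""
    seq, mot = _normalize(sequence), _normalize(motif)
    n, i = 0, seq.find(mot)
    while i != -1:
        n += 1
        i = seq.find(mot, i + 1)
    return n


def scan(cds_records: list[tuple[str, str]], motif: str) -> list[GeneHit]:
    """Count motif occurrences per CDS.

    ``cds_records`` are (header, sequence) pairs as returned by
    :func:`cleavemap.io.read_fasta`; the locus tag is taken from an NCBI-style
    ``[locus_tag=...]`` attribute when present, else the first header token.
    Records shorter than the motif simply count zero.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    hits = []
    for header, seq in cds_records:
        locus, product = _parse_header(header)
        hits.append(
            GeneHit(
                locus_tag=locus,
                cds_length=len(seq),
                occurrence_count=count_occurrences(seq, motif),
                product=product,
            )
        )
    return hits


def expected_counts(sequence: str, motif: str, order: int = 0) -> tuple[float, float]:
    """Composition-null expectation and Poisson upper-tail p for one CDS.

    Returns (expected_count, p_value) where p_value = P(X >= observed) for
    X ~ Poisson(expected_count).  Only the zeroth-order (single-base
    composition) null is implemented.
    """
    if order != 0:
        raise NotImplementedError("only the zeroth-order composition null is available")
    seq, mot = _normalize(sequence), _normalize(motif)
    if not seq:
        raise ValueError("zero-length CDS")
    m = len(mot)
    counts = Counter(b for b in seq if b in "ACGU")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("CDS contains no unambiguous bases")
    p_match = 1.0
    for b in mot:
        p_match *= counts.get(b, 0) / total
    lam = max(len(seq) - m + 1, 0) * p_match
    observed = count_occurrences(seq, mot)
    p_value = float(poisson.sf(observed - 1, lam)) if lam > 0 else (1.0 if observed == 0 else 0.0)
    return lam, p_value


def scan_with_expectation(
    cds_records: list[tuple[str, str]],
    motif: str,
    genome_wide_null: bool = False,
    fdr: bool = False,
) -> list[GeneHit]:
    """Scan plus expectation/enrichment per CDS.

    ``genome_wide_null`` uses pooled base frequencies over all records instead
    of each CDS's own composition; ``fdr`` adds Benjamini-Hochberg q-values.
    """
    hits = scan(cds_records, motif)
    mot = _normalize(motif)
    if genome_wide_null:
        pooled = Counter()
        for _, seq in cds_records:
            pooled.update(b for b in _normalize(seq) if b in "ACGU")
        total = sum(pooled.values())
        p_match = 1.0
        for b in mot:
            p_match *= pooled.get(b, 0) / total if total else 0.0
        out = []
        for hit in hits:
            lam = max(hit.cds_length - len(mot) + 1, 0) * p_match
            p = float(poisson.sf(hit.occurrence_count - 1, lam)) if lam > 0 else (
                1.0 if hit.occurrence_count == 0 else 0.0
            )
            out.append(replace(hit, expected_count=lam, p_value=p))
    else:
        out = []
        for (_, seq), hit in zip(cds_records, hits):
            lam, p = expected_counts(seq, mot)
            out.append(replace(hit, expected_count=lam, p_value=p))
    if fdr and out:
        _, q, _, _ = multipletests([h.p_value for h in out], method="fdr_bh")
        out = [replace(h, q_value=float(qi)) for h, qi in zip(out, q)]
    return out


def tabulate(hits: list[GeneHit]) -> tuple[pd.DataFrame, list[str]]:
    """Occurrence table sorted by (count desc, locus_tag) plus per-count
    summary lines of the form ``count=1: 31 genes``."""
    df = pd.DataFrame(
        {
            "locus_tag": [h.locus_tag for h in hits],
            "length_bp": [h.cds_length for h in hits],
            "occurrence_count": [h.occurrence_count for h in hits],
            "expected": [h.expected_count for h in hits],
            "p_value": [h.p_value for h in hits],
            "product": [h.product for h in hits],
        }
    )
    df = df.sort_values(
        ["occurrence_count", "locus_tag"], ascending=[False, True]
    ).reset_index(drop=True)
    summary = [
        f"count={int(c)}: {int(n)} genes"
        for c, n in df["occurrence_count"].value_counts().sort_index(ascending=False).items()
    ]
    return df, summary
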