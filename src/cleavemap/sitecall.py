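"""From reads to called cleavage sites.

Stages: barcode extraction (reads whose 5' prefix is the ligated barcode mark
genuine cleavage 5' ends), mapping back to the known substrates, per-position
coverage, the relative coverage increase (RCI) statistic, and pooled top-K
site selection.

RCI at position n is coverage(n) / coverage(n-1); when coverage(n-1) is zero,
RCI(n) is defined equal to coverage(n).  A cleavage between n-1 and n creates
a step-up in coverage whose leading edge the ratio detects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ReadRecord, Substrate

logger = logging.getLogger("cleavemap")


@dataclass(frozen=True)
class Mapping:
    read_id: str
    substrate_id: str
    start: int  # 1-based position of the read's first post-barcode base
    matched_len: int
    mismatches: int


@dataclass(frozen=True)
class CoverageProfile:
    substrate_id: str
    depth: np.ndarray  # int vector; depth[i] is coverage of position i+1

    def __len__(self) -> int:
        return len(self.depth)


@dataclass(frozen=True)
class RCIProfile:
    substrate_id: str
    rci: np.ndarray  # non-negative, finite; rci[i] is RCI of position i+1

    def __len__(self) -> int:
        return len(self.rci)


@dataclass(frozen=True)
class Site:
    """A called cleavage position: the n with high RCI.  By the window
    convention this n sits at window offset 0 and the cut lies between
    offsets -1 and 0 (i.e. between substrate positions n-1 and n)."""

    substrate_id: str
    position: int
    rci_value: float
    rank: int
    depth: int = 0


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_barcoded(
    reads: list[ReadRecord], barcode: str, max_barcode_mismatches: int = 1
) -> list[ReadRecord]:
    """Keep reads whose prefix matches the barcode with at most the allowed
    substitutions (no indels), stripping that prefix; discard all others."""
    if not barcode:
        raise ValueError("barcode must be non-empty")
    blen = len(barcode)
    kept: list[ReadRecord] = []
    for r in reads:
        if len(r.sequence) <= blen:
            continue
        prefix = r.sequence[:blen]
        if prefix != barcode and _hamming(prefix, barcode) > max_barcode_mismatches:
            continue
        kept.append(
            ReadRecord(
                id=r.id,
                sequence=r.sequence[blen:],
                qualities=r.qualities[blen:] if r.qualities is not None else None,
            )
        )
    logger.info("barcode extraction: kept %d / %d reads", len(kept), len(reads))
    return kept


def _build_seed_index(
    substrates: list[Substrate], k: int
) -> tuple[dict[str, list[tuple[str, int]]], dict[str, np.ndarray]]:
    index: dict[str, list[tuple[str, int]]] = {}
    arrays: dict[str, np.ndarray] = {}
    for sub in substrates:
        seq = sub.sequence
        arrays[sub.id] = np.frombuffer(seq.encode(), dtype=np.uint8)
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((sub.id, i + 1))
    return index, arrays


def map_reads(
    reads: list[ReadRecord],
    substrates: list[Substrate],
    max_mismatches: int = 2,
    min_match_len: int = 20,
) -> list[Mapping]:
    """Assign reads to substrate positions by exact-seed lookup and full-read
    mismatch extension.

    The seed is the first min(20, read length) bases; candidate locations are
    extended over the whole read allowing at most ``max_mismatches``
    substitutions.  Reads with zero or multiple distinct best locations are
    discarded.  T and U are treated as equivalent.
    """
    if not substrates:
        raise ValueError("substrates must be non-empty")
    seed_k = 20
    index, arrays = _build_seed_index(substrates, seed_k)
    lengths = {s.id: len(s) for s in substrates}

    mappings: list[Mapping] = []
    n_ambiguous = n_unmapped = 0
    for r in reads:
        seq = r.sequence.upper().replace("T", "U")
        if len(seq) < min_match_len:
            n_unmapped += 1
            continue
        k = min(seed_k, len(seq))
        candidates = index.get(seq[:k]) if k == seed_k else [
            (sid, pos) for key, locs in index.items() if key.startswith(seq)
            for sid, pos in locs
        ]
        if not candidates:
            n_unmapped += 1
            continue
        read_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        best: list[tuple[str, int, int, int]] = []
        best_mm = max_mismatches + 1
        for sid, pos in candidates:
            span = min(len(read_arr), lengths[sid] - pos + 1)
            if span < min_match_len:
                continue
            mm = int(
                np.count_nonzero(read_arr[:span] != arrays[sid][pos - 1 : pos - 1 + span])
            )
            if mm > max_mismatches:
                continue
            if mm < best_mm:
                best, best_mm = [(sid, pos, span, mm)], mm
            elif mm == best_mm:
                best.append((sid, pos, span, mm))
        if len(best) != 1:
            if len(best) > 1:
                n_ambiguous += 1
            else:
                n_unmapped += 1
            continue
        sid, pos, span, mm = best[0]
        mappings.append(Mapping(r.id, sid, pos, span, mm))
    logger.info(
        "mapping: %d mapped, %d unmapped, %d ambiguous of %d reads",
        len(mappings), n_unmapped, n_ambiguous, len(reads),
    )
    return mappings


def coverage(mappings: list[Mapping], substrate: Substrate) -> CoverageProfile:
    """Full-read depth: depth[n] = number of mapped reads whose interval
    [start, start + matched_len - 1] contains position n."""
    L = len(substrate)
    diff = np.zeros(L + 1, dtype=np.int64)
    for m in mappings:
        if m.substrate_id != substrate.id:
            raise ValueError(
                f"mapping for {m.substrate_id!r} passed with substrate {substrate.id!r}"
            )
        diff[m.start - 1] += 1
        diff[m.start - 1 + m.matched_len] -= 1
    depth = np.cumsum(diff[:L])
    return CoverageProfile(substrate.id, depth)


def rci(profile: CoverageProfile) -> RCIProfile:
    """Relative coverage increase with the zero-denominator rule.

    rci[n] = depth[n] / depth[n-1] when depth[n-1] > 0, else depth[n].
    Position 1 takes depth[0] as 0, hence rci[1] = depth[1].
    """
    d = profile.depth.astype(np.float64)
    prev = np.concatenate(([0.0], d[:-1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(prev > 0, d / np.where(prev > 0, prev, 1.0), d)
    return RCIProfile(profile.substrate_id, out)


def top_sites(
    rci_profiles: list[RCIProfile],
    coverage_profiles: list[CoverageProfile],
    K: int = 10,
    window_w: int = 11,
    min_depth: int = 5,
) -> list[Site]:
    """The K positions with highest RCI pooled across all substrates.

    Positions must carry at least ``min_depth`` coverage (the raw ratio is
    unstable at depth 0-1) and their ``window_w``-wide window must fit inside
    the substrate (edge positions are skipped with a warning).  Ties are
    broken by higher depth, then substrate id, then smaller position.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not rci_profiles or all(len(p) == 0 for p in rci_profiles):
        raise ValueError("no RCI profiles to rank")
    depth_by_id = {p.substrate_id: p.depth for p in coverage_profiles}
    half = window_w // 2

    candidates: list[tuple[float, int, str, int]] = []
    n_edge_skipped = 0
    for prof in rci_profiles:
        depth = depth_by_id[prof.substrate_id]
        L = len(prof)
        for n in np.nonzero(depth >= min_depth)[0] + 1:
            if n - half < 1 or n + half > L:
                if prof.rci[n - 1] > 1.0:
                    n_edge_skipped += 1
                continue
            candidates.append((float(prof.rci[n - 1]), int(depth[n - 1]), prof.substrate_id, int(n)))
    if n_edge_skipped:
        logger.warning(
            "top_sites: skipped %d eligible positions whose window runs off a substrate end",
            n_edge_skipped,
        )
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    if len(candidates) < K:
        logger.warning(
            "top_sites: only %d eligible positions for K=%d", len(candidates), K
        )
    return [
        Site(substrate_id=sid, position=pos, rci_value=r, rank=i + 1, depth=d)
        for i, (r, d, sid, pos) in enumerate(candidates[:K])
    ]
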