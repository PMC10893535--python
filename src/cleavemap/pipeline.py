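"""High-level orchestration: reads + substrates -> sites -> motif."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import PipelineConfig, ReadRecord, Substrate
from .motifcall import Motif, PFM, Window, consensus, pfm, windows
from .sitecall import (
    CoverageProfile,
    RCIProfile,
    Site,
    coverage,
    extract_barcoded,
    map_reads,
    rci,
    top_sites,
)

logger = logging.getLogger("cleavemap")


@dataclass(frozen=True)
class CallResult:
    coverage_profiles: list[CoverageProfile]
    rci_profiles: list[RCIProfile]
    sites: list[Site]
    window_list: list[Window]
    pfm: PFM
    motif: Motif


def call(
    reads: list[ReadRecord],
    substrates: list[Substrate],
    config: PipelineConfig | None = None,
) -> CallResult:
    """Run barcode extraction, mapping, coverage/RCI, top-K site selection and
    consensus motif calling under one configuration."""
    config = config or PipelineConfig()
    stripped = extract_barcoded(reads, config.barcode, config.max_barcode_mismatches)
    if not stripped:
        raise ValueError("zero barcoded reads: nothing to map")
    mappings = map_reads(
        stripped, substrates, config.max_mismatches, config.min_match_len
    )
    by_sub: dict[str, list] = {s.id: [] for s in substrates}
    for m in mappings:
        by_sub[m.substrate_id].append(m)
    cov = [coverage(by_sub[s.id], s) for s in substrates]
    rci_profiles = [rci(c) for c in cov]
    sites = top_sites(
        rci_profiles, cov, K=config.K, window_w=config.window_w,
        min_depth=config.min_depth,
    )
    window_list = windows(sites, substrates, config.window_w)
    matrix = pfm(window_list)
    motif = consensus(
        matrix, config.core_threshold, config.low_consistency_threshold
    )
    logger.info("called motif %s from %d sites", motif.annotated(), len(sites))
    return CallResult(cov, rci_profiles, sites, window_list, matrix, motif)
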