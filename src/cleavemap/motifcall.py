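"""From called sites to a consensus cleavage motif.

Windows of width w are cut from the substrate centered on each called
position (the position with high RCI sits at offset 0; the cut lies between
offsets -1 and 0).  Aligned windows give a position frequency matrix, from
which per-offset information content, a consensus core, and low-consistency
flags are derived.

The consensus core is the maximal contiguous run of offsets whose information
content reaches ``core_threshold`` bits and which contains offset 0.  With
only ~10 windows, sampling noise inflates the information content of random
flank columns (bias ~3/(2 ln2 n) bits, with fluctuations well past 0.5 bits),
so the default threshold is 1.0 bit: comfortably above the 10-window noise
floor, far below the 2 bits of an invariant column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Substrate
from .sitecall import Site

logger = logging.getLogger("cleavemap")

_BASE_ORDER = "ACGU"


@dataclass(frozen=True)
class Window:
    """A w-wide sequence window centered on a called site (offset 0 at the
    site position), N-padded where it overhangs a substrate end."""

    site: Site
    sequence: str

    @property
    def w(self) -> int:
        return len(self.sequence)

    @property
    def offsets(self) -> range:
        h = self.w // 2
        return range(-h, h + 1)


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix over (A, C, G, U) by window offset.

    N bases never contribute to counts; a column whose windows were all N is
    unusable (zero total) and its frequencies are NaN.
    """

    counts: np.ndarray  # 4 x w integers
    freqs: np.ndarray  # 4 x w reals; columns sum to 1 where usable
    n_windows: int

    @property
    def w(self) -> int:
        return self.counts.shape[1]

    @property
    def usable(self) -> np.ndarray:
        return self.counts.sum(axis=0) > 0


@dataclass(frozen=True)
class Motif:
    """Consensus cleavage motif with the cut annotated inside it.

    ``cut_before`` is the 1-based consensus position the scissile bond
    precedes; ``low_consistency_positions`` are 1-based consensus positions
    whose majority-base frequency falls below the consistency threshold.
    """

    consensus: str
    core_span: tuple[int, int]  # inclusive offsets relative to the site
    info_content: np.ndarray  # per-offset bits over the full window
    low_consistency_positions: tuple[int, ...]
    cut_before: int

    def annotated(self) -> str:
        """Consensus with '^' marking the cleavage position, e.g. U^ACAUA."""
        i = self.cut_before - 1
        return self.consensus[:i] + "^" + self.consensus[i:]


def windows(sites: list[Site], substrates: list[Substrate] | dict[str, Substrate], w: int = 11) -> list[Window]:
    """One w-wide window per site, N-padded at substrate edges."""
    if w % 2 == 0 or w < 1:
        raise ValueError(f"window width must be odd, got {w}")
    if not isinstance(substrates, dict):
        substrates = {s.id: s for s in substrates}
    half = w // 2
    out: list[Window] = []
    for site in sites:
        if site.substrate_id not in substrates:
            raise KeyError(f"site references unknown substrate {site.substrate_id!r}")
        seq = substrates[site.substrate_id].sequence
        chars = []
        for off in range(-half, half + 1):
            p = site.position + off
            chars.append(seq[p - 1] if 1 <= p <= len(seq) else "N")
        out.append(Window(site=site, sequence="".join(chars)))
    return out


def pfm(window_list: list[Window]) -> PFM:
    """Count bases per offset across windows (N excluded) and normalize."""
    if not window_list:
        raise ValueError("need at least one window")
    w = window_list[0].w
    if any(win.w != w for win in window_list):
        raise ValueError("windows have inconsistent widths")
    counts = np.zeros((4, w), dtype=np.int64)
    for win in window_list:
        for j, base in enumerate(win.sequence):
            if base != "N":
                counts[_BASE_ORDER.index(base), j] += 1
    totals = counts.sum(axis=0)
    if not np.any(totals > 0):
        raise ValueError("zero usable windows (all N)")
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = counts / np.where(totals > 0, totals, np.nan)
    return PFM(counts=counts, freqs=freqs, n_windows=len(window_list))


def info_content(matrix: PFM) -> np.ndarray:
    """Per-offset information content in bits: 2 + sum_b f log2 f, with
    0*log 0 = 0.  Unusable (all-N) columns report 0 bits.  No small-sample
    correction is applied."""
    f = matrix.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    bits = 2.0 + np.nansum(term, axis=0)
    bits[~matrix.usable] = 0.0
    return np.clip(bits, 0.0, 2.0)


def consensus(
    matrix: PFM,
    core_threshold: float = 1.0,
    low_consistency_threshold: float = 0.9,
) -> Motif:
    """Call the consensus motif from a PFM.

    The core span is the maximal contiguous run of offsets with information
    content >= ``core_threshold`` bits containing offset 0; the consensus is
    the column-majority base over that span (ties resolved in A<C<G<U order
    and logged); positions whose majority frequency is below
    ``low_consistency_threshold`` are flagged low-consistency.
    """
    if not 0.0 <= core_threshold <= 2.0:
        raise ValueError("core_threshold must be in [0, 2] bits")
    if not 0.0 < low_consistency_threshold <= 1.0:
        raise ValueError("low_consistency_threshold must be in (0, 1]")
    bits = info_content(matrix)
    w = matrix.w
    half = w // 2
    center = half  # column index of offset 0
    if bits[center] < core_threshold:
        raise ValueError(
            "no motif at called sites: information content at the site position "
            f"is {bits[center]:.2f} bits (< {core_threshold})"
        )
    lo = center
    while lo > 0 and bits[lo - 1] >= core_threshold:
        lo -= 1
    hi = center
    while hi < w - 1 and bits[hi + 1] >= core_threshold:
        hi += 1

    letters: list[str] = []
    low_flags: list[int] = []
    for pos, j in enumerate(range(lo, hi + 1), start=1):
        col = matrix.freqs[:, j]
        top = np.nanmax(col)
        winners = [b for b, f in zip(_BASE_ORDER, col) if f == top]
        if len(winners) > 1:
            logger.info(
                "consensus tie at offset %d between %s; taking %s",
                j - half, winners, winners[0],
            )
        letters.append(winners[0])
        if top < low_consistency_threshold:
            low_flags.append(pos)

    return Motif(
        consensus="".join(letters),
        core_span=(lo - half, hi - half),
        info_content=bits,
        low_consistency_positions=tuple(low_flags),
        cut_before=(0 - (lo - half)) + 1,
    )
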