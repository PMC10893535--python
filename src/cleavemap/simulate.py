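"""Synthetic-data generator: partial endoribonuclease digestion of known RNA
substrates followed by library preparation.

The generator emulates the experimental workflow the pipeline analyses:

1. a mixture of synthetic RNA substrates (1000-2000 nt) carrying planted
   UACAUA sites is partially digested, the backbone being cut between the U
   and the first A of each recognised site;
2. nonspecific background breakage occurs uniformly along each molecule;
3. fragments shorter than the size-selection cutoff (200 nt) are excluded;
4. a 45-nt RNA barcode is ligated to fragment 5' ends;
5. single-end reads are taken from the 5' end of each (barcoded) fragment,
   with i.i.d. substitution errors.

Read ids encode the originating substrate and fragment start so tests can use
them as ground truth; the analysis pipeline never parses them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import DEFAULT_BARCODE, RNA_ALPHABET, ReadRecord, Substrate

logger = logging.getLogger("cleavemap")

_BASES = np.frombuffer(b"ACGU", dtype=np.uint8)

#: Names and lengths of the eight-substrate study mixture (two ~1000-nt,
#: three ~1500-nt, three ~2000-nt RNAs).
STUDY_SUBSTRATES = (
    ("RNA1000-1", 1000),
    ("L1000-1", 1000),
    ("RNA1500-1", 1533),
    ("L1500-1", 1533),
    ("H1500-1", 1533),
    ("RNA2000-1", 2033),
    ("L2000-1", 2033),
    ("H2000-1", 2033),
)


@dataclass(frozen=True)
class DigestionModel:
    """Parameters of partial digestion, fragmentation and read sampling.

    ``cut_offset`` is the number of bases after the motif start at which the
    backbone is cut: the default 1 places the cut between the U and the first
    A of UACAUA (U^ACAUA).
    """

    motif: str = "UACAUA"
    cut_offset: int = 1
    site_cleavage_prob: float = 0.7
    background_break_rate: float = 1e-4
    n_molecules: int = 2000
    read_length: int = 150
    read_error_rate: float = 0.001

    def __post_init__(self) -> None:
        for name in ("site_cleavage_prob", "background_break_rate", "read_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 1 <= self.cut_offset <= len(self.motif):
            raise ValueError(
                f"cut_offset must be in [1, {len(self.motif)}], got {self.cut_offset}"
            )
        bad = set(self.motif) - set("ACGU")
        if bad:
            raise ValueError(f"motif contains non-RNA characters {sorted(bad)}")
        if self.n_molecules < 1 or self.read_length < 1:
            raise ValueError("n_molecules and read_length must be >= 1")


@dataclass(frozen=True)
class Fragment:
    """A contiguous piece [start, end] (1-based, closed) of one substrate."""

    substrate_id: str
    start: int
    end: int
    barcoded: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid fragment interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1


def _find_all(seq: str, motif: str) -> list[int]:
    """1-based start positions of all (overlapping) occurrences."""
    hits, i = [], seq.find(motif)
    while i != -1:
        hits.append(i + 1)
        i = seq.find(motif, i + 1)
    return hits


def make_substrate(
    length: int,
    n_sites: int,
    motif: str = "UACAUA",
    seed: int = 0,
    substrate_id: str | None = None,
    edge_margin: int = 50,
) -> Substrate:
    """Generate a random-composition RNA with exactly ``n_sites`` planted,
    non-overlapping motif occurrences and no spurious occurrence elsewhere.

    Planted sites are kept at least ``edge_margin`` bases from either end so
    windows centered on the cleavage position never run off the substrate.
    """
    m = len(motif)
    if length < n_sites * (m + 20):
        raise ValueError(
            f"length {length} too short to pack {n_sites} sites of a {m}-mer motif"
        )
    rng = np.random.default_rng(seed)
    lo, hi = edge_margin + 1, length - m - edge_margin + 1
    if n_sites > 0 and hi < lo:
        raise ValueError("edge margins leave no room for planted sites")

    sites: list[int] = []
    for _ in range(1000):
        cand = sorted(rng.integers(lo, hi + 1, size=n_sites).tolist())
        if all(b - a >= m for a, b in zip(cand, cand[1:])):
            sites = cand
            break
    else:
        raise ValueError("could not place non-overlapping sites; reduce n_sites")

    arr = rng.choice(_BASES, size=length)
    seq = list(arr.tobytes().decode())
    for s in sites:
        seq[s - 1 : s - 1 + m] = motif
    planted = set(sites)
    covered = [False] * length
    for s in sites:
        for i in range(s - 1, s - 1 + m):
            covered[i] = True
    # destroy spurious motif copies by mutating a base outside planted spans
    for _ in range(1000):
        spurious = [p for p in _find_all("".join(seq), motif) if p not in planted]
        if not spurious:
            break
        for p in spurious:
            idxs = [i for i in range(p - 1, p - 1 + m) if not covered[i]]
            if not idxs:  # cannot happen for non-self-overlapping motifs
                raise ValueError("spurious occurrence inside planted spans")
            i = int(rng.choice(idxs))
            cur = seq[i]
            seq[i] = str(rng.choice([b for b in "ACGU" if b != cur]))
    else:
        raise ValueError("failed to remove spurious motif occurrences")

    return Substrate(
        id=substrate_id or f"sub{length}x{n_sites}s{seed}",
        sequence="".join(seq),
        planted_sites=tuple(sites),
    )


def digest(substrate: Substrate, model: DigestionModel, seed: int = 0) -> list[Fragment]:
    """Partially digest ``n_molecules`` copies of a substrate.

    Each planted site is cut, independently per molecule, with probability
    ``site_cleavage_prob`` between positions (site + cut_offset - 1) and
    (site + cut_offset); background breaks fall uniformly at per-position rate
    ``background_break_rate``.  The returned fragments partition each molecule.
    """
    rng = np.random.default_rng(seed)
    L = len(substrate)
    sites = np.asarray(substrate.planted_sites or (), dtype=np.int64)
    # boundary b means a break between positions b and b+1
    site_bounds = sites + model.cut_offset - 1
    n = model.n_molecules

    cut_mask = (
        rng.random((n, len(site_bounds))) < model.site_cleavage_prob
        if len(site_bounds)
        else np.zeros((n, 0), dtype=bool)
    )
    bg_counts = (
        rng.binomial(L - 1, model.background_break_rate, size=n)
        if L > 1 and model.background_break_rate > 0
        else np.zeros(n, dtype=np.int64)
    )

    fragments: list[Fragment] = []
    for i in range(n):
        bounds = set(site_bounds[cut_mask[i]].tolist())
        if bg_counts[i]:
            bounds.update(rng.integers(1, L, size=bg_counts[i]).tolist())
        start = 1
        for b in sorted(bounds):
            fragments.append(Fragment(substrate.id, start, int(b)))
            start = int(b) + 1
        fragments.append(Fragment(substrate.id, start, L))
    return fragments


def size_select(fragments: list[Fragment], min_fragment_len: int = 200) -> list[Fragment]:
    """Drop fragments shorter than the size-selection cutoff, preserving order."""
    return [f for f in fragments if len(f) >= min_fragment_len]


def ligate_barcode(
    fragments: list[Fragment],
    barcode: str = DEFAULT_BARCODE,
    ligation_prob: float = 0.9,
    seed: int = 0,
) -> list[Fragment]:
    """Mark each fragment barcoded independently with ``ligation_prob``.

    Conceptually the barcode is prepended at the fragment's 5' end — the
    cleavage-generated end; the sequence itself is attached at read time.
    """
    bad = set(barcode) - RNA_ALPHABET
    if bad:
        raise ValueError(f"barcode contains non-RNA characters {sorted(bad)}")
    if not 0.0 <= ligation_prob <= 1.0:
        raise ValueError("ligation_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    flags = rng.random(len(fragments)) < ligation_prob
    return [
        Fragment(f.substrate_id, f.start, f.end, barcoded=bool(b))
        for f, b in zip(fragments, flags)
    ]


def fragments_to_reads(
    substrates: dict[str, Substrate] | list[Substrate],
    fragments: list[Fragment],
    model: DigestionModel,
    seed: int = 0,
    barcode: str = DEFAULT_BARCODE,
    n_reads: int | None = None,
) -> list[ReadRecord]:
    """Sample single-end 5'-anchored reads from fragments.

    Each read is the 5' prefix of (barcode + fragment) for barcoded fragments,
    or of the fragment alone otherwise, truncated to ``read_length``, with
    i.i.d. substitution errors at ``read_error_rate``.  If ``n_reads`` is
    given, fragments are sampled with replacement to that depth; otherwise one
    read per fragment is emitted.
    """
    if not isinstance(substrates, dict):
        substrates = {s.id: s for s in substrates}
    rng = np.random.default_rng(seed)
    if n_reads is None:
        chosen = range(len(fragments))
    else:
        if not fragments:
            raise ValueError("cannot sample reads from an empty fragment list")
        chosen = rng.integers(0, len(fragments), size=n_reads).tolist()

    seqs: list[str] = []
    meta: list[Fragment] = []
    for fi in chosen:
        frag = fragments[fi]
        sub = substrates[frag.substrate_id]
        insert = sub.sequence[frag.start - 1 : frag.end]
        full = (barcode + insert) if frag.barcoded else insert
        seqs.append(full[: model.read_length])
        meta.append(frag)

    if model.read_error_rate > 0 and seqs:
        lens = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
        n_err = rng.binomial(lens, model.read_error_rate)
        for i in np.nonzero(n_err)[0]:
            s = list(seqs[i])
            for j in rng.choice(len(s), size=n_err[i], replace=False):
                s[j] = "ACGU"[(("ACGU".index(s[j]) if s[j] in "ACGU" else 0) + int(rng.integers(1, 4))) % 4]
            seqs[i] = "".join(s)

    reads: list[ReadRecord] = []
    for i, (frag, seq) in enumerate(zip(meta, seqs)):
        tag = "B" if frag.barcoded else "U"
        reads.append(
            ReadRecord(
                id=f"r{i}|{frag.substrate_id}|{frag.start}|{tag}",
                sequence=seq,
                qualities="I" * len(seq),
            )
        )
    return reads


def simulate_study(
    seed: int = 0,
    model: DigestionModel | None = None,
    n_reads: int = 50_000,
    ligation_prob: float = 0.9,
    min_fragment_len: int = 200,
    barcode: str = DEFAULT_BARCODE,
    sites_range: tuple[int, int] = (2, 4),
) -> tuple[list[Substrate], list[ReadRecord]]:
    """End-to-end generation under the study conditions: eight substrates of
    1000-2000 nt carrying 2-4 planted motif sites each, partial digestion,
    200-nt size selection, barcode ligation and read sampling.
    """
    model = model or DigestionModel()
    rng = np.random.default_rng(seed)
    substrates: list[Substrate] = []
    all_fragments: list[Fragment] = []
    for k, (name, length) in enumerate(STUDY_SUBSTRATES):
        n_sites = int(rng.integers(sites_range[0], sites_range[1] + 1))
        sub = make_substrate(
            length, n_sites, model.motif,
            seed=int(rng.integers(0, 2**31)), substrate_id=name,
        )
        substrates.append(sub)
        all_fragments.extend(digest(sub, model, seed=int(rng.integers(0, 2**31))))
    kept = size_select(all_fragments, min_fragment_len)
    kept = ligate_barcode(kept, barcode, ligation_prob, seed=int(rng.integers(0, 2**31)))
    reads = fragments_to_reads(
        substrates, kept, model,
        seed=int(rng.integers(0, 2**31)), barcode=barcode, n_reads=n_reads,
    )
    logger.info(
        "simulated %d substrates, %d fragments after size selection, %d reads",
        len(substrates), len(kept), len(reads),
    )
    return substrates, reads
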