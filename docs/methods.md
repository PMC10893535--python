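# Methods

## Digestion and library model (`cleavemap.simulate`)

The generator emulates partial digestion of a mixture of eight synthetic RNA
substrates (two of ~1000 nt, three of ~1533 nt, three of ~2033 nt), each
carrying 2–4 planted, non-overlapping UACAUA sites kept ≥50 nt from the
ends. Per molecule, each site is cut independently with probability
`site_cleavage_prob` (default **0.7**) between the U and the first A
(`cut_offset = 1`); nonspecific backbone breaks occur uniformly at
`background_break_rate` per position (default **1e-4**). The per-position
uniform background is a neutral choice — no nonspecific fragmentation model
is implied by the chemistry — and is a configuration knob. Fragments then
pass a 200-nt size selection, receive the fixed 45-nt barcode on their 5'
end with ligation efficiency 0.9, and single-end 5'-anchored reads are
sampled with replacement to 50,000 total (default), 150 nt long, with i.i.d.
substitution errors at 1e-3. Read length, depth, molecule count (2,000 per
substrate) and ligation efficiency are free parameters chosen as realistic
values for a desktop-scale MiSeq-style experiment; they are not dictated by
the protocol being emulated.

Reads are single-end and 5'-anchored because the statistic consumes only the
fragment 5' end that the barcode marks; paired ends would add no
information. Ground truth (substrate, fragment start) is carried in read ids
for test oracles and never parsed by the pipeline.

**What the generator does not emulate:** reverse-transcription and adapter
biases, realistic quality-score trajectories, indels, and — importantly —
impurity among the top windows. Windows are cut from the reference, so when
all top-K sites are true sites the motif columns are perfectly conserved and
no low-consistency flags arise. Passing tests therefore demonstrate recovery
of a planted signal under sampling noise, not robustness to the partially
degenerate site lists real digestions produce; the probe-design stage is
exercised directly on the degenerate motif state instead.

## Site calling (`cleavemap.sitecall`)

Barcode extraction keeps reads whose prefix matches the 45-mer with ≤1
substitution (no indels) and strips it. Mapping is a bespoke exact-seed
(first 20 bases) lookup over the known substrates with full-read extension
allowing ≤2 substitutions; ambiguous (multiple equally good loci) and
unassignable reads are discarded. Against short, known, synthetic references
this makes the discard rules explicit and avoids an aligner dependency.

Coverage is full-read depth. RCI uses the divide-with-zero rule above
(position 1 takes coverage(0) = 0). Top-K selection (K = 10) pools positions
across substrates and requires depth ≥ 5 — the raw ratio is unstable on
0/1-depth positions; the floor is configurable because the protocol itself
states none — and skips positions whose 11-base window would run off a
substrate end. Ties break by higher depth, then substrate id, then smaller
position, making the ranking fully deterministic.

## Motif calling (`cleavemap.motifcall`)

Windows are 11 nt, N-padded at edges, with the called position at offset 0;
the cut always lies between offsets −1 and 0. The PFM excludes N. Information
content per column is 2 + Σ_b f·log₂f bits (0·log 0 = 0), without
small-sample correction.

The consensus core is the maximal contiguous run of columns with
≥ `core_threshold` bits containing offset 0. **Default 1.0 bit.** With only
n = 10 windows, a uniformly random column's observed information content is
biased upward by ≈ 3/(2·ln2·n) ≈ 0.22 bits and exceeds 0.5 bits with
probability ≈ 0.14 (exceeds 1.0 bit with ≈ 0.007), so a 0.5-bit cutoff would
routinely absorb random flank columns into the core; 1.0 bit sits above the
10-window noise floor and far below the 2 bits of a conserved column.
Majority-base ties resolve in A<C<G<U order (logged). Columns whose majority
frequency is < 0.9 are flagged low-consistency.

## Probe design and curve classification (`cleavemap.fretprobe`)

The probe set is the consensus insert plus, per low-consistency position,
its three substitution variants (enumerated U, A, C, G minus the consensus
base), each flanked by five deoxyadenosines with 5' 6-FAM / 3' BHQ-1 — so
1 + 3·(#flagged positions) probes; for UACAUA with positions {1, 4, 6}
flagged, ten probes.

Cleavage kinetics are pseudo-first-order, F(t) = F₀ + A(1 − e^(−kt)) +
Gaussian noise; k is recovered by nonlinear least squares on the
replicate-averaged curve. The verdict compares the sample's endpoint rise
above the control's initial intensity against `fold_threshold` (default 2)
times the larger of the control's own endpoint rise and the control's noise
scale (std of its first differences / √2). Using baseline-subtracted rises
and a data-derived noise floor keeps the verdict invariant under affine
rescaling of the recorded intensities applied to sample and control alike,
and prevents a flat but noisy control from producing an arbitrarily large
fold change. The threshold separating "notable increase" from "no change"
is operational, not asserted by the underlying assay.

## Genome scanning (`cleavemap.genome_scan`)

Sense-strand only (transcripts are the substrate), overlapping matches
counted, T ≡ U. The null is zeroth-order: with the CDS's own base
frequencies f, a window matches with p = Π f(motifⱼ), the expectation over
L − m + 1 windows is λ = (L−m+1)p, and P(X ≥ observed | Poisson(λ)) is the
enrichment statistic. Per-CDS composition is the conservative local choice
for a genome with high, heterogeneous G+C; a pooled genome-wide-frequency
mode and Benjamini–Hochberg q-values are available behind flags, with raw
p-values reported by default. Output headers label the null explicitly —
this operationalisation is declared by the package, not inherited from the
assay it mirrors.

## Pairwise alignment (`cleavemap.seqcompare`)

Needleman–Wunsch with affine gaps via Biopython's `PairwiseAligner`
(deterministic first optimal traceback), defaults BLOSUM62 / open 10 /
extend 0.5 — the community defaults for pairwise protein comparison.
Identity and similarity are EMBOSS conventions: identical (resp. positively
scoring) columns over the full alignment length including gap columns. Over
a gap-free 120-column alignment, 65.0% identity and 85.8% similarity
correspond uniquely to 78 and 103 columns, which the test suite verifies by
integer enumeration and by aligning a synthetic pair built from exactly
those column types.

## Problem sizes and determinism

Tests run the full study-scale simulation (50,000 reads, 16,000 molecules)
in ~1 s per seed; the headline recovery check repeats it over 20 seeds. All
randomness flows through `numpy.random.default_rng` seeds; every simulated
artefact is byte-reproducible from (seed, config).

## Known limitations

- The mapper handles substitutions only; indel-bearing reads are discarded.
- Degenerate (IUPAC) consensus output is not supported — the consensus is a
  single majority sequence, matching how the motif is reported downstream.
- The composition null ignores codon structure and dinucleotide bias; it is
  a declared stand-in, and enrichment p-values should be read accordingly.
- Low-consistency flags cannot arise from the current generator (see above),
  so the probe-design path is validated on constructed motif states.
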