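"""Global protein alignment with EMBOSS-style identity/similarity.

Needleman-Wunsch with affine gaps (BLOSUM62, open 10, extend 0.5); identity
is the fraction of identical columns over the full alignment length and
similarity additionally admits positively scoring substitutions.  The demo
pair below is synthetic (two diverged copies of a short sequence).
"""

import numpy as np

import cleavemap as cm

rng = np.random.default_rng(1)
aa = list("ACDEFGHIKLMNPQRSTVWY")
a = "".join(rng.choice(aa, 90))
b = list(a)
for i in rng.choice(90, size=25, replace=False):  # diverge ~28% of residues
    b[i] = str(rng.choice([x for x in aa if x != b[i]]))
b = "".join(b[:40] + b[43:])  # and delete three residues

aln = cm.global_align(a, b)
print(aln.report())
print()
print(f"identity   {aln.identity_pct:5.1f}%  ({aln.n_identical}/{aln.alignment_length} identical columns)")
print(f"similarity {aln.similarity_pct:5.1f}%  ({aln.n_similar}/{aln.alignment_length} positively scoring columns)")
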