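"""Per-species nucleotide diversity on a toy alignment.

Pi is the mean over sequence pairs of (differing shared sites) / (shared
sites); pairs sharing no more than half the alignment are discarded by the
overlap rule.
"""

from macrodiv import diversity

seqs = [
    "ACGTACGTAC",
    "ACGTACGTAT",  # 1 difference in 10 shared sites -> 0.1
    "ACGTACCTAT",  # vs seq0: 2/10, vs seq1: 1/10
    "ACGT------",  # only 4 shared columns: overlap 0.4, pairs excluded
]
result = diversity.nucleotide_diversity(seqs)
print(f"n sequences   : {result.n}")
print(f"pairs usable  : {result.n_pairs_used} of 6 (overlap rule removed 3)")
print(f"Pi            : {result.pi:.4f}")
# Expected: mean of 1/10, 2/10, 1/10 = 0.1333 over the three usable pairs.

pair = diversity.pairwise_stats("AA--", "AAAA")
print(f"gapped pair   : k={pair.k} m={pair.m} overlap={pair.overlap_fraction}")
# overlap 0.5 is NOT > 0.5, so this pair would be dropped.
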