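"""Paired statistical comparison of two coding systems on 53 mentions.

Reconstructs the bookkeeping of a 53-mention test set in which one system
codes 42 mentions correctly and another only 31, with all 11 discordant
mentions won by the first system.  Prints the accuracies, their
difference, the exact McNemar tails, and a sign-flip permutation p.
"""

from pathocode.evaluation import compare_systems

n = 53
gold = [f"m{i}" for i in range(n)]
fusion = [gold[i] if i < 42 else "wrong" for i in range(n)]
sparse = [gold[i] if i < 31 else "wrong" for i in range(n)]

report = compare_systems(gold, sparse, fusion, n_perm=10_000, seed=0)
print(f"accuracy (sparse system):  {report.accuracy_a:.4f}")
print(f"accuracy (fusion system):  {report.accuracy_b:.4f}")
print(f"accuracy difference:       {report.accuracy_difference:.4f}")
print(f"discordant pairs:          b={report.mcnemar_b}, c={report.mcnemar_c}")
print(f"McNemar exact two-sided p: {report.mcnemar_p:.4f}")
print(f"McNemar exact one-sided p: {report.mcnemar_p_one_sided:.4f}")
print(f"permutation p (10k iter):  {report.permutation_p:.4f}")
# An 11-0 discordance split at n=53 gives a 0.2075 accuracy difference and
# a one-sided exact p of 2^-11 ~ 0.0005: the difference is far beyond what
# chance swapping of per-mention outcomes produces.
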