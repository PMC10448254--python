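"""Choose the window size: random-hit rates of shuffled (k+1)-mers.

For each k, the reference sequences are concatenated, shuffled, and the
fraction of random windows found in the true window multiset at least
w_min times is averaged over replicates. Small k saturates (every window
is a random hit: matches carry no signal); large k makes almost every true
window unique (shared sequence between genomes becomes invisible). The
working point sits between the two regimes."""

from mitodbg import SimSpec, generate_clade, rhit_experiment, \
    unique_kmer_stats

clade = generate_clade(SimSpec(seed=3))
genomes = clade.genomes

print("k\tw_min\tmean r_hit\tsd")
for k in (2, 6, 10, 14):
    for res in rhit_experiment(genomes, k, w_mins=(1, 4), replicates=10,
                               seed=7):
        print(f"{res.k}\t{res.w_min}\t{res.mean:.4f}\t\t{res.sd:.4f}")

print("\nk\tdistinct\tof 4^(k+1)\tunique in multiset")
for k in (2, 6, 10, 14):
    distinct, frac_possible, frac_unique = unique_kmer_stats(genomes, k)
    print(f"{k}\t{distinct}\t\t{frac_possible:.2e}\t{frac_unique:.3f}")
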