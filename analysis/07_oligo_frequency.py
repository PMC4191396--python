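#!/usr/bin/env python
"""CG-containing oligonucleotide frequencies on toy genomes.

Counts overlapping di-/tri-/tetranucleotide windows containing the CG step
in random toy FASTA sequences (reverse-complement pooled, normalized per
counted window), illustrating the genomic counting rules on synthetic
input rather than whole genomes.
"""

from pathlib import Path

from cgtwist.io import count_cg_oligos
from cgtwist.synthgen import make_toy_fasta

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    # GC-poor toy "genome": CG windows are rare, as in real genomes
    fasta = make_toy_fasta({"n": 5, "length": 50_000, "gc": 0.40}, seed=701)
    for k in (2, 3, 4):
        table = count_cg_oligos(fasta, k)
        table.to_csv(RESULTS / f"oligo_freq_k{k}.tsv", sep="\t")
        top = table.sort_values("pooled_count", ascending=False).head(3)
        tops = ", ".join(f"{i} ({int(r.pooled_count)})" for i, r in top.iterrows())
        print(f"k={k}: {len(table)} CG-containing k-mer classes; most common: {tops}")
    print("wrote results/oligo_freq_k{2,3,4}.tsv")


if __name__ == "__main__":
    main()
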