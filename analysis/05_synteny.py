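#!/usr/bin/env python
"""Gene-order collinearity of the focal genome against each comparator.

Reduces each genome pair to a signed permutation of shared genes and reports
maximal collinear blocks; writes results/05_synteny.tsv.
"""

from pathlib import Path

from plastokit.io import read_plastome
from plastokit.synteny import collinear_blocks, shared_gene_permutation, synteny_summary

SPECIES = ("U_pinnatifida", "S_japonica", "E_siliculosus", "F_vesiculosus")


def main() -> None:
    base = Path("scratch/genomes")
    records = {}
    for sp in SPECIES:
        fasta = base / f"{sp}.fasta"
        if not fasta.exists():
            raise SystemExit(f"{fasta} missing; run analysis/01_simulate_genomes.py first")
        records[sp] = read_plastome(fasta, "fasta+gff3")

    rows = ["pair\tn_shared\tn_blocks\tlargest_block\tfraction_in_blocks\t"
            "inverted_blocks\tprivate_genes"]
    focal = records["U_pinnatifida"]
    for sp in SPECIES[1:]:
        perm = shared_gene_permutation(focal, records[sp])
        blocks = collinear_blocks(perm)
        s = synteny_summary(blocks)
        inverted = sum(1 for b in blocks if b.orientation == "inverted" and b.length >= 2)
        private = ",".join(sorted(set(perm.excluded_a) | set(perm.excluded_b))) or "."
        print(f"U_pinnatifida vs {sp}: {len(perm.order)} shared genes in "
              f"{s['n_blocks']} blocks (largest {s['largest_block']}, "
              f"{inverted} inverted); private: {private}")
        rows.append(
            f"U_pinnatifida-{sp}\t{len(perm.order)}\t{s['n_blocks']}\t"
            f"{s['largest_block']}\t{s['fraction_in_blocks']:.4f}\t{inverted}\t{private}"
        )
    Path("results/05_synteny.tsv").write_text("\n".join(rows) + "\n")
    print("table -> results/05_synteny.tsv")


if __name__ == "__main__":
    main()
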