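#!/usr/bin/env python
"""Start/stop codon census, gene inventory, and gene overlaps per genome.

Produces the comparison-table-shaped results/03_codon_usage.tsv (species x
codon categories) and results/03_overlaps.tsv.
"""

from pathlib import Path

from plastokit.census import codon_census, find_overlaps, gene_inventory
from plastokit.io import read_plastome

SPECIES = ("U_pinnatifida", "S_japonica", "E_siliculosus", "F_vesiculosus")


def main() -> None:
    codon_rows = ["species\tATG\tGTG\tATT\tTAA\tTAG\tTGA\tGTG_genes\tATT_genes"]
    overlap_rows = ["species\tgeneA\tgeneB\toverlap_nt\tsame_strand"]
    for species in SPECIES:
        fasta = Path("scratch/genomes") / f"{species}.fasta"
        if not fasta.exists():
            raise SystemExit(f"{fasta} missing; run analysis/01_simulate_genomes.py first")
        rec = read_plastome(fasta, "fasta+gff3")
        cc = codon_census(rec)
        inv = gene_inventory(rec)
        gtg = ",".join(sorted(cc.genes_with_start("GTG"))) or "."
        att = ",".join(sorted(cc.genes_with_start("ATT"))) or "."
        codon_rows.append(
            f"{species}\t{cc.starts['ATG']}\t{cc.starts['GTG']}\t{cc.starts['ATT']}\t"
            f"{cc.stops['TAA']}\t{cc.stops['TAG']}\t{cc.stops['TGA']}\t{gtg}\t{att}"
        )
        print(f"{species}: {inv['CDS']} CDS; starts ATG={cc.starts['ATG']} "
              f"GTG={cc.starts['GTG']} ({gtg}) ATT={cc.starts['ATT']} ({att}); "
              f"stops TAA={cc.stops['TAA']} TAG={cc.stops['TAG']} TGA={cc.stops['TGA']}")
        for a, b, ov, same in find_overlaps(rec).pairs:
            overlap_rows.append(f"{species}\t{a}\t{b}\t{ov}\t{same}")
    Path("results/03_codon_usage.tsv").write_text("\n".join(codon_rows) + "\n")
    Path("results/03_overlaps.tsv").write_text("\n".join(overlap_rows) + "\n")
    print("tables -> results/03_codon_usage.tsv, results/03_overlaps.tsv")


if __name__ == "__main__":
    main()
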