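"""End-to-end orchestration of the analysis stages.

A single config drives: genome acquisition (synthetic presets or files),
read recruitment, contig ordering, architecture detection, codon census,
element detection, synteny and the marker-gene phylogeny.  Every stage writes
into one JSON-serializable report; all randomness derives from the root seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import architecture as arch
from . import census as census_mod
from . import elements, phylo, recruit, synteny
from .io import read_plastome
from .records import PlastokitError, PlastomeRecord, extract_cds
from .simulate import paper_config, random_decoy, simulate_plastome, simulate_reads

logger = logging.getLogger(__name__)

DEFAULT_SPECIES = ("U_pinnatifida", "S_japonica", "E_siliculosus", "F_vesiculosus")


class PipelineStageError(PlastokitError):
    """A stage failed; ``report`` holds everything computed before the failure."""

    def __init__(self, stage: str, message: str, report: dict):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.report = report


@dataclass
class PipelineConfig:
    seed: int = 0
    species: tuple[str, ...] = DEFAULT_SPECIES
    genomes: tuple[dict, ...] = ()  # overrides species: {name, path, format, annotation?}
    stages: dict[str, bool] = field(default_factory=lambda: {
        "recruit": True, "order": True, "architecture": True, "census": True,
        "elements": True, "synteny": True, "phylo": True,
    })
    k: int = 21
    min_containment: float = 0.5
    min_ir: int = 1000
    min_span: int = 40
    n_reads: int = 2000
    read_len: int = 100
    plastid_fraction: float = 0.6
    bootstrap_replicates: int = 100
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PlastokitError(f"unknown config keys: {sorted(unknown)}")
        if "species" in raw:
            raw["species"] = tuple(raw["species"])
        if "genomes" in raw:
            raw["genomes"] = tuple(raw["genomes"])
        return cls(**raw)


def _load_genomes(config: PipelineConfig) -> list[PlastomeRecord]:
    if config.genomes:
        return [
            read_plastome(g["path"], g.get("format", "fasta+gff3"),
                          annotation=g.get("annotation"))
            for g in config.genomes
        ]
    return [simulate_plastome(paper_config(sp, seed=config.seed)) for sp in config.species]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; halts with a stage-named error on failure."""
    report: dict = {
        "tool": "plastokit",
        "version": "0.1.0",
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    for g in config.genomes:  # pre-flight: fail before any stage runs
        for key in ("path", "annotation"):
            p = g.get(key)
            if p is not None and not Path(p).exists():
                raise PipelineStageError("preflight", f"input file {p} not found", report)
    stage = "load"
    try:
        records = _load_genomes(config)
        target, comparators = records[0], records[1:]
        report["genomes"] = [r.sequence.name for r in records]

        if config.stages.get("recruit", True):
            stage = "recruit"
            index = recruit.build_index([r.sequence for r in records], k=config.k)
            decoy = random_decoy(50000, seed=config.seed)
            reads = simulate_reads(target, decoy, config.n_reads, config.read_len,
                                   config.plastid_fraction, seed=config.seed)
            kept = recruit.classify_reads(reads, index, config.min_containment)
            kept_ids = {r[0] for r in kept.reads}
            tp = sum(1 for r in reads.reads if r[2] == "plastid" and r[0] in kept_ids)
            fp = len(kept.reads) - tp
            fn = sum(1 for r in reads.reads if r[2] == "plastid") - tp
            report["stages"]["recruit"] = {
                "n_reads": len(reads.reads),
                "n_recruited": len(kept.reads),
                "recall": tp / (tp + fn) if tp + fn else 0.0,
                "precision": tp / (tp + fp) if tp + fp else 0.0,
            }

        if config.stages.get("order", True):
            stage = "order"
            rng_offsets = range(0, len(target.sequence) - 5000, 9973)
            contigs = {
                f"contig{i}": target.sequence.fetch(off, off + 5000)
                for i, off in enumerate(rng_offsets)
            }
            placed, unplaced = recruit.order_contigs(contigs, target, anchor_k=config.k)
            report["stages"]["order"] = {
                "n_contigs": len(contigs),
                "n_placed": len(placed),
                "n_unplaceable": len(unplaced),
                "in_input_order": [p.name for p in placed],
            }

        if config.stages.get("architecture", True):
            stage = "architecture"
            block = {}
            for rec in records:
                quad = arch.detect_quadripartite(rec.sequence, min_ir=config.min_ir)
                comp = arch.base_composition(rec.sequence)
                block[rec.sequence.name] = {
                    "total": len(rec.sequence),
                    "at_percent": round(100 * comp["AT"], 2),
                    "regions": None if quad is None else {
                        "lsc": quad.lengths["lsc"], "ssc": quad.lengths["ssc"],
                        "ir": quad.lengths["ir"],
                    },
                }
            report["stages"]["architecture"] = block

        if config.stages.get("census", True):
            stage = "census"
            block = {}
            for rec in records:
                cc = census_mod.codon_census(rec)
                inv = census_mod.gene_inventory(rec)
                overlaps = census_mod.find_overlaps(rec)
                block[rec.sequence.name] = {
                    "starts": cc.starts, "stops": cc.stops,
                    "n_skipped": len(cc.skipped),
                    "inventory": inv,
                    "overlaps": [
                        {"genes": f"{a}-{b}", "nt": ov, "same_strand": same}
                        for a, b, ov, same in overlaps.pairs
                    ],
                }
            report["stages"]["census"] = block

        if config.stages.get("elements", True):
            stage = "elements"
            pals = elements.find_palindromes(target, min_span=config.min_span,
                                             intergenic_only=True)
            polys = []
            if comparators:
                other = comparators[0]
                for gene in ("ycf35", "ilvB"):
                    fa = next((f for f in target.features if f.name == gene), None)
                    fb = next((f for f in other.features if f.name == gene), None)
                    if fa is None or fb is None:
                        continue
                    for poly in elements.compare_ortholog_repeats(
                        extract_cds(target, fa), extract_cds(other, fb), gene=gene
                    ):
                        polys.append({
                            "gene": poly.gene, "unit": poly.unit,
                            "copies_a": poly.copies_a, "copies_b": poly.copies_b,
                            "delta_nt": poly.delta_nt,
                            "frame_preserved": poly.frame_preserved,
                        })
            report["stages"]["elements"] = {
                "palindromes": [
                    {"span": p.span, "start": p.interval[0],
                     "flanks": [p.flank_upstream, p.flank_downstream]}
                    for p in pals
                ],
                "repeat_polymorphisms": polys,
            }

        if config.stages.get("synteny", True) and comparators:
            stage = "synteny"
            block = {}
            for other in comparators:
                perm = synteny.shared_gene_permutation(target, other)
                blocks = synteny.collinear_blocks(perm)
                summary = synteny_summary_dict(blocks)
                summary["excluded"] = sorted(set(perm.excluded_a) | set(perm.excluded_b))
                block[other.sequence.name] = summary
            report["stages"]["synteny"] = block

        if config.stages.get("phylo", True) and len(records) >= 3:
            stage = "phylo"
            markers = phylo.extract_markers(records)
            families = {g: phylo.align_protein_family(s) for g, s in markers.genes.items()}
            aln = phylo.concatenate(families, markers.taxa, order=phylo.DEFAULT_MARKERS)
            dist = phylo.distance_matrix(aln)
            tree = phylo.nj_tree(dist)
            consensus = phylo.bootstrap_consensus(
                aln, replicates=config.bootstrap_replicates, seed=config.seed
            )
            report["stages"]["phylo"] = {
                "n_markers": len(families),
                "alignment_width": aln.width,
                "nj_newick": tree.newick(),
                "consensus_newick": consensus.newick(),
            }
    except PlastokitError as exc:
        raise PipelineStageError(stage, str(exc), report) from exc

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report


def synteny_summary_dict(blocks) -> dict:
    summary = synteny.synteny_summary(blocks)
    summary["blocks"] = [
        {"genes": len(b.genes), "orientation": b.orientation} for b in blocks
    ]
    return summary
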