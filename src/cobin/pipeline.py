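"""Config-driven orchestration of the binning-first-and-assembly-later flow.

Stages per species: classify (Kraken2 adapter or built-in fixture
classifier) -> cobarcode refinement -> assembly (toy or external) ->
ANI/AF decontamination -> evaluation.  Species are processed independently
in taxid order, so a failure in one species never blocks the others; the
manifest records every species' outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import assemble, decontam, evaluate, refine, taxonomy
from .io import (
    ClassificationRecord,
    FastaRecord,
    ReadPairRecord,
    parse_fasta,
    parse_kraken_classifications,
    parse_taxonomy_table,
    read_stlfr_fastq,
    write_fasta,
    write_kraken_classifications,
    write_stlfr_fastq,
)

logger = logging.getLogger("cobin")

FIXTURE = "fixture"


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; mirrors the YAML config file."""

    reads_fwd: str = ""
    reads_rev: str = ""
    references: str = ""
    taxonomy: str = ""
    classifications: str | None = None  # Kraken2 output; None -> fixture classifier
    outdir: str = "cobin_out"
    classifier_k: int = 31
    refinement: refine.RefinementConfig = field(default_factory=refine.RefinementConfig)
    ani_min: float = 90.0
    af_min: float = 0.5
    identity_min: float = 95.0
    min_alignment_len: int = 10_000
    assembler: str = assemble.TOY
    assembler_cmd: str | None = None
    assembly_k: int = 31
    min_kmer_count: int = 2
    seed: int = 0
    parallel_species: int = 8  # interface knob; execution is sequential

    def __post_init__(self) -> None:
        if not 0 <= self.ani_min <= 100 or not 0 <= self.identity_min <= 100:
            raise ValueError("identity thresholds must be within [0, 100]")
        if not 0 <= self.af_min <= 1:
            raise ValueError("af_min must be within [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        refinement = refine.RefinementConfig(**data.pop("refinement", {}))
        return cls(refinement=refinement, **data)


@dataclass
class SpeciesOutcome:
    taxid: int
    name: str
    status: str  # ok | skipped: abundance | failed: <stage>
    abundance: float = 0.0
    n_refined_reads: int = 0
    n_contigs: int = 0
    n_contigs_kept: int = 0
    total_bases: int = 0
    n50: int = 0
    ng50: int = 0
    genome_fraction: float = 0.0
    assembly_path: str = ""


@dataclass
class PipelineResult:
    outcomes: list[SpeciesOutcome]
    outdir: Path

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame([vars(o) for o in self.outcomes])

    @property
    def failed(self) -> bool:
        return any(o.status.startswith("failed") for o in self.outcomes)


def classify_with_fixture(
    reads: Sequence[ReadPairRecord],
    references: Sequence[FastaRecord],
    tree: taxonomy.TaxonomyTree,
    k: int = 31,
) -> list[ClassificationRecord]:
    """Build the fixture k-mer index over the references and classify reads."""
    name_to_taxid = tree.name_to_taxid()
    ref_tuples = []
    for rec in references:
        if rec.id not in name_to_taxid:
            raise ValueError(f"reference {rec.id!r} absent from the taxonomy")
        ref_tuples.append((rec.id, name_to_taxid[rec.id], rec.seq))
    index = taxonomy.build_kmer_index(ref_tuples, tree, k=k)
    return taxonomy.classify_reads_fixture(reads, index, tree)


def run_pipeline(
    config: PipelineConfig,
    reads: Sequence[ReadPairRecord] | None = None,
    references: Sequence[FastaRecord] | None = None,
    tree: taxonomy.TaxonomyTree | None = None,
    classifications: Sequence[ClassificationRecord] | None = None,
) -> PipelineResult:
    """Execute the full flow; inputs may be passed in memory or read from
    the paths in ``config``.  Returns the per-species manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if reads is None:
        reads = list(read_stlfr_fastq(config.reads_fwd, config.reads_rev))
    if references is None:
        references = parse_fasta(config.references)
    if tree is None:
        tree = parse_taxonomy_table(config.taxonomy)
    if classifications is None:
        if config.classifications is None:
            logger.info("classifying %d read pairs with the fixture classifier", len(reads))
            classifications = classify_with_fixture(
                reads, references, tree, k=config.classifier_k
            )
            write_kraken_classifications(classifications, outdir / "classifications.tsv")
        else:
            classifications = list(parse_kraken_classifications(config.classifications))

    name_to_taxid = tree.name_to_taxid()
    ref_by_taxid = {name_to_taxid[r.id]: r for r in references}
    reference_lengths = {t: len(r.seq) for t, r in ref_by_taxid.items()}

    logger.info("refining %d species", len(reference_lengths))
    refinement = refine.refine_all_species(
        classifications, reads, reference_lengths, tree, config.refinement
    )
    refinement.report().to_csv(outdir / "refinement_report.tsv", sep="\t", index=False)

    reads_by_id = {r.read_id: r for r in reads}
    outcomes: list[SpeciesOutcome] = []
    for taxid in sorted(reference_lengths):
        ref_rec = ref_by_taxid[taxid]
        name = ref_rec.id
        if taxid in refinement.skipped:
            outcomes.append(
                SpeciesOutcome(taxid, name, "skipped: abundance",
                               abundance=refinement.skipped[taxid])
            )
            continue
        read_set = refinement.read_sets[taxid]
        species_dir = outdir / f"species_{taxid}"
        species_dir.mkdir(exist_ok=True)
        try:
            refined = [reads_by_id[i] for i in sorted(read_set.refined_read_ids)]
            fq1 = species_dir / "refined_1.fq"
            fq2 = species_dir / "refined_2.fq"
            write_stlfr_fastq(refined, fq1, fq2)
            if config.assembler == assemble.TOY:
                contig_set = assemble.toy_debruijn_assemble(
                    refined, k=config.assembly_k,
                    min_kmer_count=config.min_kmer_count, species=taxid,
                )
            else:
                if not config.assembler_cmd:
                    raise ValueError("external assembler requires assembler_cmd")
                contig_set = assemble.run_external_assembler(
                    fq1, fq2, config.assembler_cmd, species_dir, species=taxid
                )
            cleaned, report, alignments = decontam.decontaminate(
                contig_set, (ref_rec.id, ref_rec.seq),
                ani_min=config.ani_min, af_min=config.af_min,
            )
            report.to_csv(species_dir / "decontamination_report.tsv", sep="\t", index=False)
            fasta_path = species_dir / "assembly.cleaned.fasta"
            if cleaned.contigs:
                write_fasta(cleaned.records(), fasta_path)
            kept_ids = {cid for cid, _ in cleaned.contigs}
            kept_alignments = [a for a in alignments if a.query_id in kept_ids]
            metrics = evaluate.evaluate_assembly(
                cleaned, (ref_rec.id, ref_rec.seq), kept_alignments, config.identity_min
            )
            outcomes.append(
                SpeciesOutcome(
                    taxid, name, "ok",
                    abundance=read_set.abundance,
                    n_refined_reads=len(read_set.refined_read_ids),
                    n_contigs=len(contig_set.contigs),
                    n_contigs_kept=len(cleaned.contigs),
                    total_bases=metrics["total_bases"],
                    n50=metrics["n50"],
                    ng50=metrics["ng50"],
                    genome_fraction=metrics["genome_fraction"],
                    assembly_path=str(fasta_path) if cleaned.contigs else "",
                )
            )
            logger.info(
                "species %s (%d): %d contigs kept, NG50 %d, genome fraction %.1f%%",
                name, taxid, len(cleaned.contigs), metrics["ng50"],
                metrics["genome_fraction"],
            )
        except Exception as exc:  # per-species isolation: record and continue
            logger.exception("species %s (%d) failed", name, taxid)
            outcomes.append(
                SpeciesOutcome(taxid, name, f"failed: {exc}",
                               abundance=read_set.abundance)
            )
    result = PipelineResult(outcomes, outdir)
    result.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return result
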