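"""End-to-end orchestration: preprocess -> alnfilter -> cluster -> build ->
classify -> quantify -> stats, with a run manifest.

The transcript annotation is built only from the samples flagged
``build_annotation`` (typically the deeply sequenced conditions);
quantification then runs every sample against that fixed annotation, so
counts stay comparable across all samples.
"""

from __future__ import annotations

import json
import time
from collections import defaultdict
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from .alnfilter import JunctionChain, filter_bam, write_chains_tsv
from .config import PipelineConfig
from .gtfio import write_gtf
from .isoformbuild import (TranscriptModel, apply_locus_rules, build_loci,
                           collapse_reads, deseq2_export,
                           final_annotation_filter, filter_transcripts,
                           quantify)
from .novelty import (NoveltyCall, ReferenceAnnotation, classify_all,
                      write_novelty_tsv)
from .preprocess import preprocess_fastq
from .sitecluster import (ClusterParams, _snap, assign_reads_to_tags,
                          build_tag_index, junction_sides, write_tags_bed)
from .stats import predict_nmd, test_exon_pairs, test_isoform_usage


def load_genome(path) -> dict:
    """Genome as chrom -> str (plain dict; adequate for desk-scale FASTA)."""
    genome = {}
    name = None
    parts: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line.upper())
    if name is not None:
        genome[name] = "".join(parts)
    return genome


def _ambiguity_fractions(
    final_transcripts: List[TranscriptModel],
    discarded: List[JunctionChain],
    tags,
    params: ClusterParams,
) -> Dict[str, float]:
    """Attribute tag-unassignable chains to final transcripts.

    A discarded chain is attributed when its partially snapped chain
    (unassignable ends as wildcards) matches exactly one final transcript.
    The returned fraction per transcript is ambiguous / (ambiguous + clean)
    member junction chains.
    """
    pos_index = {key: [t.position for t in tag_list]
                 for key, tag_list in tags.items()}
    by_len = defaultdict(list)
    for t in final_transcripts:
        by_len[(t.chrom, t.strand, len(t.intron_chain))].append(t)
    ambiguous = defaultdict(int)
    for chain in discarded:
        left_side, right_side = junction_sides(chain.strand)
        snapped = []
        for start, end in chain.introns:
            s = _snap(start, pos_index.get(
                (chain.chrom, chain.strand, left_side), []), params.dist_thresh)
            e = _snap(end, pos_index.get(
                (chain.chrom, chain.strand, right_side), []), params.dist_thresh)
            snapped.append((s, e))
        candidates = []
        for t in by_len.get((chain.chrom, chain.strand, len(snapped)), []):
            if all((s is None or s == ts) and (e is None or e == te)
                   for (s, e), (ts, te) in zip(snapped, t.intron_chain)):
                candidates.append(t)
        if len(candidates) == 1:
            ambiguous[candidates[0].transcript_id] += 1
    fractions = {}
    for t in final_transcripts:
        amb = ambiguous.get(t.transcript_id, 0)
        if amb:
            fractions[t.transcript_id] = amb / (amb + t.read_count)
    return fractions


def run_pipeline(config: PipelineConfig, out_dir, force: bool = False) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        if manifest.get("completed"):
            manifest["skipped_up_to_date"] = True
            return manifest

    if not config.samples:
        raise ValueError("config has no samples")
    if config.genome_fasta is None:
        raise ValueError("config.genome_fasta is required")
    genome = load_genome(config.genome_fasta)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "counts": {},
    }
    report: dict = {}

    # stage 1-2: per-sample read processing and alignment filtering
    chains_by_sample: Dict[str, List[JunctionChain]] = {}
    for sample in config.samples:
        if sample.bam is None:
            raise FileNotFoundError(
                f"sample {sample.sample_id}: no alignment file configured")
        fl_flags: Dict[str, bool] = {}
        if sample.fastq is not None:
            processed = preprocess_fastq(
                sample.fastq,
                out_fastq=out / f"{sample.sample_id}.trimmed.fastq",
                out_tsv=out / f"{sample.sample_id}.reads.tsv",
                qscore_cutoff=config.qscore_cutoff,
                window=config.end_window,
                min_identity=config.adapter_min_identity,
                min_length=config.min_read_length,
                report=report,
            )
            fl_flags = {p.read_id: p.is_full_length for p in processed}
        chains = filter_bam(
            sample.bam, genome, full_length_flags=fl_flags or None,
            max_softclip=config.max_softclip,
            max_junction_insert=config.max_junction_insert,
            junction_window=config.junction_insert_window,
            sample=sample.sample_id, report=report,
        )
        chains_by_sample[sample.sample_id] = chains
        write_chains_tsv(chains, out / f"{sample.sample_id}.chains.tsv")
    manifest["stages"] += ["preprocess", "alnfilter"]

    # stage 3: tag splice sites from annotation-building samples
    params = ClusterParams(config.hfwinsize, config.disthres,
                           config.pthreshold, config.sumhold)
    anno_samples = [s.sample_id for s in config.samples if s.build_annotation]
    anno_chains = [c for s in anno_samples for c in chains_by_sample[s]]
    tags = build_tag_index(anno_chains, params, genome=genome)
    write_tags_bed(tags, out / "tags.bed")
    manifest["stages"].append("cluster")

    # stage 4: snap every sample's chains onto the tags
    tagged_by_sample: Dict[str, List[JunctionChain]] = {}
    discarded_anno: List[JunctionChain] = []
    for sample_id, chains in chains_by_sample.items():
        tagged, discarded = assign_reads_to_tags(chains, tags, params, report)
        tagged_by_sample[sample_id] = tagged
        if sample_id in anno_samples:
            discarded_anno.extend(discarded)

    # stage 5: build the annotation
    anno_tagged = [c for s in anno_samples for c in tagged_by_sample[s]]
    drafts = collapse_reads(anno_tagged)
    drafts = filter_transcripts(
        drafts, genome, min_count=config.min_read_count,
        min_full_length_fraction=config.min_full_length_fraction,
        polya_distance=config.polya_distance)
    loci = build_loci(drafts)
    drafts = apply_locus_rules(
        loci, drafts, genome,
        min_fraction_of_max=config.locus_min_fraction,
        truncation_rescue_fraction=config.truncation_rescue_fraction,
        misalignment_check=config.misalignment_check)
    if config.reference_gtf is not None:
        reference = ReferenceAnnotation.from_gtf(config.reference_gtf)
    else:
        reference = ReferenceAnnotation()
    final = final_annotation_filter(drafts, reference)
    build_loci(final)  # rescued transcripts need locus ids too
    manifest["stages"].append("build")
    manifest["counts"]["draft_transcripts"] = len(drafts)
    manifest["counts"]["final_transcripts"] = len(final)
    manifest["counts"]["loci"] = len({t.locus_id for t in final})

    # stage 6: novelty classification
    amb = _ambiguity_fractions(final, discarded_anno, tags, params)
    calls = classify_all(final, reference, ambiguous_fractions=amb)
    write_novelty_tsv(calls, out / "novelty.tsv")
    calls_by_id = {c.transcript_id: c for c in calls}
    write_gtf(final, out / "annotation.gtf", novelty_by_id=calls_by_id)
    manifest["stages"].append("classify")
    manifest["counts"]["novel_transcripts"] = sum(
        1 for c in calls if c.status == "novel")

    # stage 7: quantification of all samples against the fixed annotation
    counts, gene_counts, unassigned = quantify(final, tagged_by_sample)
    counts.to_csv(out / "transcript_counts.tsv", sep="\t")
    gene_counts.to_csv(out / "gene_counts.tsv", sep="\t")
    deseq2_export(counts, config.de_prefilter_min_total).to_csv(
        out / "transcript_counts_deseq2.tsv", sep="\t")
    manifest["stages"].append("quantify")
    manifest["counts"]["unassigned_chains"] = int(unassigned.sum())

    # stage 8: downstream statistics
    genes = defaultdict(list)
    for t in final:
        genes[t.locus_id].append(t)
    chain_to_locus = {(t.chrom, t.strand, t.intron_chain): t.locus_id
                      for t in final}
    reads_by_gene = defaultdict(list)
    for chains in tagged_by_sample.values():
        for c in chains:
            locus = chain_to_locus.get((c.chrom, c.strand, c.introns))
            if locus is not None:
                reads_by_gene[locus].append(c)
    pair_tests = test_exon_pairs(genes, reads_by_gene)
    with open(out / "exon_pairs.tsv", "w") as fh:
        fh.write("gene_id\texon_a\texon_b\tn_both\tn_a_only\tn_b_only"
                 "\tn_neither\tadjacency\tdirection\tp_value\tp_adjusted\n")
        for t in pair_tests:
            tb = t.table
            fh.write(f"{tb.gene_id}\t{tb.exon_a[0]}-{tb.exon_a[1]}"
                     f"\t{tb.exon_b[0]}-{tb.exon_b[1]}\t{tb.n_both}"
                     f"\t{tb.n_a_only}\t{tb.n_b_only}\t{tb.n_neither}"
                     f"\t{tb.adjacency}\t{t.odds_direction}"
                     f"\t{t.p_value:.6g}\t{t.p_adjusted:.6g}\n")
    nmd_calls = [predict_nmd(t, reference, genome,
                             distance_threshold=config.nmd_distance)
                 for t in final
                 if calls_by_id[t.transcript_id].status == "novel"]
    with open(out / "nmd.tsv", "w") as fh:
        fh.write("transcript_id\tstart_codon_source\tdistance\tis_nmd"
                 "\tno_call_reason\n")
        for c in nmd_calls:
            fh.write(f"{c.transcript_id}\t{c.start_codon_source or '.'}"
                     f"\t{'' if c.stop_to_last_junction_distance is None else c.stop_to_last_junction_distance}"
                     f"\t{int(c.is_nmd)}\t{c.no_call_reason or '.'}\n")

    conditions = sorted({s.condition for s in config.samples if s.condition})
    if len(conditions) == 2:
        summed = counts.T.groupby(
            [next(s.condition for s in config.samples
                  if s.sample_id == c) for c in counts.columns]).sum().T
        summed["locus_id"] = [t.locus_id for t in final]
        usage = test_isoform_usage(summed)
        usage.to_csv(out / "isoform_usage.tsv", sep="\t", index=False)
        manifest["counts"]["usage_tests"] = len(usage)
    manifest["stages"].append("stats")
    manifest["counts"]["exon_pair_tests"] = len(pair_tests)
    manifest["counts"].update({k: v for k, v in report.items()})

    manifest["completed"] = True
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
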