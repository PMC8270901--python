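"""GTF export of the final annotation.

Internal coordinates are 0-based half-open; GTF is 1-based inclusive, so
conversion happens only here.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional

from .isoformbuild import TranscriptModel


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path,
    novelty_by_id: Optional[Dict[str, object]] = None,
    source: str = "fulquant",
) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = [f'gene_id "{t.locus_id or t.transcript_id}"',
                     f'transcript_id "{t.transcript_id}"',
                     f'read_count "{t.read_count}"',
                     f'full_length_fraction "{t.full_length_fraction:.3f}"',
                     f'status "{t.status}"']
            if novelty_by_id and t.transcript_id in novelty_by_id:
                call = novelty_by_id[t.transcript_id]
                attrs.append(f'novelty "{call.status}"')
                if call.status == "novel":
                    attrs.append(f'novelty_category "{call.category}"')
            attr_str = "; ".join(attrs) + ";"
            fh.write("\t".join([
                t.chrom, source, "transcript", str(t.start + 1), str(t.end),
                ".", t.strand, ".", attr_str]) + "\n")
            for s, e in t.exons:
                fh.write("\t".join([
                    t.chrom, source, "exon", str(s + 1), str(e), ".",
                    t.strand, ".", attr_str]) + "\n")
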