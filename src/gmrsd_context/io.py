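"""Tabular and sequence I/O for pipeline artifacts.

ORF tables and domain-hit tables are plain TSV (hmmscan-domtblout-style
columns for hits); sequences travel as FASTA, trees as Newick with supports
in internal-node labels.  Coordinates are 1-based closed on disk.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .architecture import (
    ArchClass,
    DomainHit,
    GenomeInventory,
    MergedPair,
    ProteinArchitecture,
)
from .enrichment import ORF, EnrichmentResult, GenomeAnnotation

ORF_COLUMNS = ["genome", "contig", "orf_index", "start", "end", "strand", "protein_id"]
DOMAIN_COLUMNS = ["protein_id", "domain_id", "env_start", "env_end", "evalue", "model_coverage"]


def write_orf_table(genomes: Sequence[GenomeAnnotation], path: str | Path) -> None:
    rows = [
        (g.genome_id, o.contig_id, o.orf_index, o.start, o.end, o.strand, o.protein_id)
        for g in genomes
        for orfs in g.contigs.values()
        for o in orfs
    ]
    pd.DataFrame(rows, columns=ORF_COLUMNS).to_csv(path, sep="\t", index=False)


def read_orf_table(path: str | Path) -> list[GenomeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"genome": str, "contig": str, "strand": str})
    genomes = []
    for genome_id, gdf in df.groupby("genome", sort=True):
        contigs = {}
        for contig_id, cdf in gdf.groupby("contig", sort=True):
            cdf = cdf.sort_values("orf_index")
            contigs[contig_id] = tuple(
                ORF(contig_id, int(r.orf_index), int(r.start), int(r.end), r.strand, r.protein_id)
                for r in cdf.itertuples()
            )
        genomes.append(GenomeAnnotation(genome_id=genome_id, contigs=contigs))
    return genomes


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    rows = [
        (h.protein_id, h.domain_id, h.env_start, h.env_end, h.evalue, h.model_coverage)
        for h in hits
    ]
    pd.DataFrame(rows, columns=DOMAIN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_domain_table(path: str | Path) -> dict[str, list[DomainHit]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[DomainHit]] = {}
    for r in df.itertuples():
        out.setdefault(r.protein_id, []).append(
            DomainHit(
                r.protein_id, r.domain_id, int(r.env_start), int(r.env_end),
                float(r.evalue), float(r.model_coverage),
            )
        )
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_architectures(archs: Sequence[ProteinArchitecture], path: str | Path,
                        genome_of: Mapping[str, str] | None = None) -> None:
    rows = []
    for a in archs:
        rows.append(
            {
                "protein_id": a.protein_id,
                "genome": (genome_of or {}).get(a.protein_id, ""),
                "class": a.klass.value,
                "extra_domains": ",".join(a.extra_domains),
                "s_start": a.s_region[0] if a.s_region else "",
                "s_end": a.s_region[1] if a.s_region else "",
                "d_start": a.d_region[0] if a.d_region else "",
                "d_end": a.d_region[1] if a.d_region else "",
                "flags": ",".join(a.flags),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_inventory(inventories: Sequence[GenomeInventory], path: str | Path) -> None:
    rows = [
        (i.genome_id, i.n_double, i.n_s_only, i.n_d_only, i.n_other)
        for i in inventories
    ]
    pd.DataFrame(
        rows, columns=["genome", "n_double", "n_s_only", "n_d_only", "n_other"]
    ).to_csv(path, sep="\t", index=False)


def write_merged_pairs(pairs: Sequence[MergedPair], path: str | Path) -> None:
    write_fasta({p.merged_id: p.merged_sequence for p in pairs}, path)


def write_enrichment_report(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    rows = [
        (
            r.domain_id, r.x1, r.n1, r.x2, r.n2, r.p1, r.p2, r.diff,
            r.ci_lower, r.ci_upper, r.conf_level, r.enriched, r.rank,
        )
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=[
            "domain", "x1", "n1", "x2", "n2", "p1", "p2", "diff",
            "ci_lower", "ci_upper", "level", "enriched", "rank",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
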