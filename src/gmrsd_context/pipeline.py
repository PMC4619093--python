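"""End-to-end pipeline orchestration over the synthetic-data stages.

``run_pipeline`` executes the seven analysis stages (simulate, architecture,
merge-msa, conservation, motifs, enrichment, coevolution) into a run
directory and writes a manifest with the config hash, the seed and a SHA-256
digest of every output so that reruns with identical config and seed are
verifiably identical.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from . import io
from .architecture import (
    ArchClass,
    accept_domain_hits,
    build_inventory,
    classify_architecture,
    pair_single_domains,
)
from .config import PipelineConfig
from .coevolution import Association, coevolution_analysis, tanglegram_export
from .enrichment import neighborhood_enrichment
from .motifs import SIGNATURE_MOTIFS, compile_motif, scan_alignment_consensus, scan_motif
from .msa import conservation_profile, merge_alignments
from .simulate import (
    FamilySimSpec,
    GenomeSimSpec,
    TreeSimSpec,
    simulate_family,
    simulate_genomes,
    simulate_tree_pair,
)

__all__ = ["run_pipeline", "summarize", "STAGES"]

STAGES = (
    "simulate",
    "architecture",
    "merge_msa",
    "conservation",
    "motifs",
    "enrichment",
    "coevolution",
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on synthetic data; returns the manifest (also written).

    Re-running with an identical config (including seed) reproduces
    byte-identical stage outputs.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    files: dict[str, list[str]] = {stage: [] for stage in STAGES}

    def emit(stage: str, name: str) -> Path:
        files[stage].append(name)
        return out / name

    # --- stage 1: simulate -------------------------------------------------
    gspec = GenomeSimSpec(**{"seed": seed, "window_k": config.window_k, **config.genome_sim})
    fspec = FamilySimSpec(**{"seed": seed + 1, **config.family_sim})
    tspec = TreeSimSpec(**{"seed": seed + 2, **config.tree_sim})
    genomes_sim = simulate_genomes(gspec)
    family_sim = simulate_family(fspec)
    tree_sim = simulate_tree_pair(tspec)

    io.write_orf_table(genomes_sim.genomes, emit("simulate", "orfs.tsv"))
    io.write_domain_table(genomes_sim.all_hits(), emit("simulate", "domains.tsv"))
    io.write_fasta(family_sim.sequences(), emit("simulate", "family.fasta"))
    io.write_domain_table(
        [h for hs in family_sim.hits_by_protein().values() for h in hs],
        emit("simulate", "family_domains.tsv"),
    )
    (emit("simulate", "tree_s.nwk")).write_text(tree_sim.newick_s + "\n")
    (emit("simulate", "tree_d.nwk")).write_text(tree_sim.newick_d + "\n")
    io.write_json(
        {
            "enriched_domains": sorted(genomes_sim.truth),
            "focal_proteins": {g: list(p) for g, p in genomes_sim.focal_proteins.items()},
            "family_motifs": {
                m.seq_id: [[t.pattern_name, t.start, t.end] for t in m.motifs]
                for m in family_sim.members
            },
        },
        emit("simulate", "truth.json"),
    )

    # --- stage 2: architecture --------------------------------------------
    by_genome: dict[str, list] = {}
    genome_of: dict[str, str] = {}
    archs = []
    for member in family_sim.members:
        accepted = accept_domain_hits(
            list(member.hits), config.evalue_domain_accept, config.coverage_min
        )
        arch = classify_architecture(accepted)
        archs.append(arch)
        by_genome.setdefault(member.genome_id, []).append(arch)
        genome_of[member.seq_id] = member.genome_id
    inventories = build_inventory(by_genome)
    pairs = pair_single_domains(inventories, by_genome, family_sim.sequences())
    io.write_architectures(archs, emit("architecture", "architectures.tsv"), genome_of)
    io.write_inventory(inventories, emit("architecture", "inventory.tsv"))
    io.write_merged_pairs(pairs, emit("architecture", "merged_pairs.fasta"))

    # --- stage 3: merge the S-extended and D-extended alignments -----------
    family_aln = family_sim.alignment()
    doubles = [m.seq_id for m in family_sim.members if m.label is ArchClass.DOUBLE]
    s_only = [m.seq_id for m in family_sim.members if m.label is ArchClass.GMRS_ONLY]
    d_only = [m.seq_id for m in family_sim.members if m.label is ArchClass.GMRD_ONLY]
    merged_path = emit("merge_msa", "merged_alignment.fasta")
    if doubles:
        aln_a = family_aln.restrict(doubles + s_only).drop_allgap_columns()
        aln_b = family_aln.restrict(doubles + d_only).drop_allgap_columns()
        merged = merge_alignments(aln_a, aln_b, doubles)
    else:
        merged = family_aln
    merged.to_fasta(merged_path)

    # --- stage 4: conservation profile -------------------------------------
    profile = conservation_profile(merged, threshold=config.conservation_threshold)
    pd.DataFrame(
        {
            "column": range(1, len(profile) + 1),
            "modal_residue": [m or "" for m in profile.modal],
            "frequency": profile.frequency,
            "plus_mark": profile.plus_mark,
        }
    ).to_csv(emit("conservation", "conservation.tsv"), sep="\t", index=False)

    # --- stage 5: motif scanning -------------------------------------------
    patterns = [compile_motif(text, name=name) for name, text in SIGNATURE_MOTIFS.items()]
    rows = []
    for member in family_sim.members:
        for pattern in patterns:
            for match in scan_motif(member.sequence, pattern, seq_id=member.seq_id):
                rows.append((match.seq_id, match.pattern_name, match.start, match.end))
    pd.DataFrame(rows, columns=["seq_id", "pattern", "start", "end"]).to_csv(
        emit("motifs", "motif_matches.tsv"), sep="\t", index=False
    )
    consensus = scan_alignment_consensus(merged, patterns, min_column_freq=0.5)
    io.write_json(
        {name: [list(w) for w in windows] for name, windows in consensus.items()},
        emit("motifs", "motif_consensus.json"),
    )

    # --- stage 6: neighborhood enrichment -----------------------------------
    table, results, windows = neighborhood_enrichment(
        list(genomes_sim.genomes),
        genomes_sim.hits_by_protein,
        genomes_sim.focal_proteins,
        k=config.window_k,
        evalue_max=config.evalue_neighborhood,
        alpha=config.alpha,
        rank_direction=config.rank_direction,
    )
    io.write_enrichment_report(results, emit("enrichment", "enrichment.tsv"))
    pd.DataFrame(
        [(w.focal_protein_id, len(w.neighbor_protein_ids), w.truncated) for w in windows],
        columns=["focal", "n_neighbors", "truncated"],
    ).to_csv(emit("enrichment", "windows.tsv"), sep="\t", index=False)

    # --- stage 7: coevolution ----------------------------------------------
    assoc = Association(tree_sim.association, tuple("double" for _ in tree_sim.association))
    ps, pd_tree, report = coevolution_analysis(
        tree_sim.tree_s, tree_sim.tree_d, assoc, config.support_threshold
    )
    paths = tanglegram_export(ps, pd_tree, assoc, out, prefix="tanglegram")
    for p in paths.values():
        files["coevolution"].append(p.name)
    io.write_json(
        {
            "rf": report.rf,
            "rf_normalized": report.rf_normalized,
            "n_shared_pairs": report.n_shared_pairs,
            "n_pruned_s": report.n_pruned_s,
            "n_pruned_d": report.n_pruned_d,
        },
        emit("coevolution", "congruence.json"),
    )

    config.to_yaml(out / "config.yaml")
    manifest = {
        "config_sha256": config.digest(),
        "seed": seed,
        "stages": {
            stage: {name: _sha256(out / name) for name in names}
            for stage, names in files.items()
        },
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest


def summarize(run_dir: str | Path) -> str:
    """Human-readable report over a completed (or partial) run directory."""
    run = Path(run_dir)
    if not run.is_dir() or not any(run.iterdir()):
        raise FileNotFoundError(f"not a run directory: {run}")
    lines = ["# GmrSD context pipeline report", ""]

    inv_path = run / "inventory.tsv"
    lines.append("## Genome inventory (double / S-only / D-only / other)")
    if inv_path.exists():
        inv = pd.read_csv(inv_path, sep="\t")
        tot = inv[["n_double", "n_s_only", "n_d_only", "n_other"]].sum()
        lines.append(
            f"{len(inv)} genomes: {tot.n_double} double, {tot.n_s_only} S-only, "
            f"{tot.n_d_only} D-only, {tot.n_other} other"
        )
    else:
        lines.append("MISSING")
    lines.append("")

    enr_path = run / "enrichment.tsv"
    lines.append("## Most enriched domains in the GmrSD neighborhood")
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t")
        called = enr[enr["enriched"]]
        lines.append(f"{len(called)} of {len(enr)} domains enriched")
        for r in enr.head(10).itertuples():
            mark = "*" if r.enriched else " "
            lines.append(
                f" {mark} {r.domain}  diff={r.diff:+.4f}  CI=[{r.ci_lower:+.4f}, {r.ci_upper:+.4f}]"
            )
    else:
        lines.append("MISSING")
    lines.append("")

    motif_path = run / "motif_matches.tsv"
    lines.append("## Signature motif matches")
    if motif_path.exists():
        mm = pd.read_csv(motif_path, sep="\t")
        for pattern, count in mm.groupby("pattern").size().items():
            lines.append(f"  {pattern}: {count} matches")
    else:
        lines.append("MISSING")
    lines.append("")

    cong_path = run / "congruence.json"
    lines.append("## GmrS/GmrD tree congruence")
    if cong_path.exists():
        rep = io.read_json(cong_path)
        lines.append(
            f"RF = {rep['rf']} (normalized {rep['rf_normalized']:.3f}) over "
            f"{rep['n_shared_pairs']} associated pairs"
        )
    else:
        lines.append("MISSING")
    return "\n".join(lines) + "\n"
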