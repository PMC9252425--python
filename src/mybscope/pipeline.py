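"""End-to-end pipeline driver over the synthetic fixture.

Runs every stage in dependency order on generated inputs with planted
truth, writes one TSV per stage plus a machine-readable run manifest
(package version, seed, parameter values, output checksums).  Identical
configuration yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from . import curation, domains, expression, grn, motifs, simulate
from .io import PipelineConfig, write_fasta, write_gff3, write_tsv


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- stage 1: synthetic family + domain annotation -------------------
    tpl = simulate.CanonicalDomainTemplate()
    fam_spec = simulate.FamilySimSpec(
        n_true_r2r3=config.n_true_r2r3,
        n_decoys_per_kind=config.n_decoys_per_kind,
        mutation_rate=config.mutation_rate, seed=seed)
    seqs, truth = simulate.simulate_family(fam_spec, tpl)
    write_fasta(seqs, out / "proteins.fa")
    write_tsv(truth, out / "family_truth.tsv", index=False)

    profile = domains.profile_from_template(tpl, seed=seed + 1)
    anns = domains.annotate_all(
        seqs, profile, tpl, score_threshold_bits=config.scan_threshold_bits)
    write_tsv(domains.hits_table(anns), out / "hits.tsv", index=False)
    class_rows = [dict(sequence_id=s, myb_class=a.myb_class,
                       n_repeats=a.n_repeats,
                       integrity_pass=bool(a.integrity_pass),
                       reason=a.integrity_reason or "")
                  for s, a in anns.items()]
    write_tsv(pd.DataFrame(class_rows), out / "classification.tsv", index=False)

    doms = {s: seqs[s][a.r2.start - 1: a.r2.start - 1 + tpl.length]
            for s, a in anns.items()
            if a.myb_class == "R2R3" and a.integrity_pass}
    logo = domains.compute_logo(doms) if len(doms) >= 2 else pd.DataFrame()
    write_tsv(logo, out / "logo.tsv")

    # --- stage 2: gene models + curation ---------------------------------
    genes, gene_truth = simulate.simulate_gene_models(
        n_genes=max(config.n_true_r2r3, 2), seed=seed + 2)
    write_gff3(genes, out / "models.gff3")
    iso_pass = {iso.mrna_id: iso.domain_ok
                for g in genes for iso in g.isoforms}
    curated = curation.curate_family(genes, iso_pass)
    write_tsv(curated, out / "family.tsv", index=False)

    # --- stage 3: motif clades -------------------------------------------
    ps = {mid: simulate.make_motif_matrix(cons, mid) for mid, cons in {
        "PS1": "WDEKLRAMYCE", "PS2": "HNIKQWFAMGD", "PS3": "CYQRTPLENVW",
        "PS4": "MGDHAWKYLTR", "PS5": "ENQFCVMIRGA", "motif12": "KRTYWQPLDSH",
    }.items()}
    assignments = {"seqA_1": ["PS1", "motif12"], "seqA_2": ["PS1", "motif12"],
                   "seqB_1": ["PS1", "PS2"], "seqB_2": ["PS1", "PS2"],
                   "sequ_1": ["PS3"], "seqbas_1": ["PS4", "PS5"],
                   "plain_1": [], "plain_2": []}
    mseqs = simulate.plant_motifs_in_sequences(assignments, ps, seed=seed + 3)
    table = motifs.build_presence_table(
        mseqs, list(ps.values()), config.motif_threshold_fraction)
    clades = motifs.classify_clades(table)
    write_tsv(table.present, out / "motif_presence.tsv")
    write_tsv(clades, out / "clades.tsv", index=False)

    # --- stage 4: qPCR ----------------------------------------------------
    folds = {("TdMYBsim1", "leaf", 12.0): 7.8,
             ("TdMYBsim1", "root", 12.0): 1.0,
             ("TdMYBsim2", "root", 12.0): 0.25}
    ct, qtruth = simulate.simulate_qpcr(folds, ct_noise_sd=0.1,
                                        reference_gene=config.reference_gene,
                                        seed=seed + 4)
    write_tsv(ct, out / "ct.tsv", index=False)
    rel = pd.concat([
        expression.delta_delta_ct(ct, g, config.reference_gene)
        for g in sorted({k[0] for k in folds})])
    write_tsv(rel, out / "relative_expression.tsv", index=False)

    # --- stage 5: GRN + enrichment ---------------------------------------
    grn_spec = simulate.GrnSimSpec(n_genes=60, n_tfs=8, n_samples=40,
                                   noise_sd=0.3, seed=seed + 5)
    counts, tpm, tfs, true_edges = simulate.simulate_grn_expression(grn_spec)
    expressed = expression.filter_expressed(tpm, config.tpm_threshold)
    edges = grn.infer_network(expressed, [t for t in tfs if t in expressed.index],
                              n_trees=config.n_trees, seed=seed + 6)
    top = grn.prune_top_edges(edges, k=min(config.top_k, len(edges)))
    write_tsv(top, out / "edges.tsv", index=False)
    sub, degrees = grn.extract_subnetwork(top, tfs[:3])
    write_tsv(sub, out / "subnetwork.tsv", index=False)

    ann, gtruth = simulate.simulate_go_annotation(
        n_genes=400, n_categories=20, planted_category_size=25,
        target_set_overlap=1.0, seed=seed + 7)
    enr = grn.go_enrichment(gtruth["target_set"], ann, gtruth["universe"],
                            min_size=config.go_min_size,
                            max_size=config.go_max_size,
                            n_permutations=min(config.go_permutations, 200),
                            seed=seed + 8)
    write_tsv(enr, out / "enrichment.tsv", index=False)

    manifest = dict(
        package="mybscope", version=__version__,
        config=dataclasses.asdict(config),
        outputs={p.name: _sha256(p) for p in sorted(out.iterdir())
                 if p.suffix in (".tsv", ".fa", ".gff3")},
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
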