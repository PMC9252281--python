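"""End-to-end pipeline orchestration.

Stages (in order): simulate -> scan -> reconstruct -> select -> refine-orfs
-> composite -> kzfp -> annotate -> evaluate. Every stage reads its inputs
from files persisted by earlier stages and writes its outputs under the run
directory, so any stage can be re-run in isolation; a manifest records every
artifact with a checksum. The configured seed propagates to every stochastic
stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align as _align
from . import annotate as _annotate
from . import kzfp as _kzfp
from . import orfs as _orfs
from . import phylo as _phylo
from . import selection as _selection
from . import seqio
from . import simulate as _simulate

log = logging.getLogger("l1forge")

STAGES = ["simulate", "scan", "reconstruct", "select", "refine-orfs",
          "composite", "kzfp", "annotate", "evaluate"]


@dataclass
class PipelineConfig:
    """Run configuration; see DEFAULTS for the full parameter block."""

    seed: int = 1
    outdir: str = "l1forge_run"
    n_subfamilies: int = 3
    total_length: int = 6500
    copies_per_subfamily: int = 30
    divergence_per_copy: float = 0.05
    succession_divergence: float = 0.05
    truncation_prob: float = 0.7
    indel_rate: float = 0.002
    spacer_mean: int = 20000
    gold_tail_length: int = 900
    gold_noise_rate: float = 0.02
    library_noise_rate: float = 0.02
    kzfp_enabled: bool = True
    kzfp_site_offset: int = 6200
    kzfp_loss_at: int | None = None   # 0-based subfamily index, or None
    n_background_peaks: int = 50
    e_cutoff_young: float = 1e-6
    e_cutoff_old: float = 1e-3
    old_classes: list[str] = field(default_factory=list)
    max_hits: int = 100
    min_hit_length: int = 3000
    max_gap_frac: float = 0.9
    join_gap: int = 50
    overlap_min: int = 30
    overlap_min_old: int = 150

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


class Pipeline:
    """Stage runner bound to a config and an output directory."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.root = Path(config.outdir)
        self.root.mkdir(parents=True, exist_ok=True)
        self.cfg.to_yaml(self.root / "config.yaml")

    # -- helpers -----------------------------------------------------------

    def _dir(self, stage: str) -> Path:
        d = self.root / stage.replace("-", "_")
        d.mkdir(exist_ok=True)
        return d

    def _evolution_params(self) -> _simulate.EvolutionParams:
        c = self.cfg
        return _simulate.EvolutionParams(
            copies_per_subfamily=c.copies_per_subfamily,
            divergence_per_copy=c.divergence_per_copy,
            succession_divergence=c.succession_divergence,
            truncation_prob=c.truncation_prob,
            indel_rate=c.indel_rate,
            seed=c.seed,
        )

    # -- stages ------------------------------------------------------------

    def simulate(self) -> None:
        c = self.cfg
        out = self._dir("simulate")
        sites = []
        if c.kzfp_enabled:
            sites = [(_simulate.DEFAULT_KZFP_ID, c.kzfp_site_offset, True)]
        spec = _simulate.ProgenitorSpec(total_length=c.total_length,
                                        kzfp_sites=sites)
        root = _simulate.simulate_progenitor(spec, seed=c.seed)
        params = self._evolution_params()
        events = []
        if c.kzfp_enabled and c.kzfp_loss_at is not None:
            events = [(c.kzfp_loss_at, _simulate.DEFAULT_KZFP_ID, "loss")]
        succession = _simulate.evolve_succession(root, c.n_subfamilies,
                                                 params, site_events=events)
        succession = [_simulate.generate_copies(t, params) for t in succession]
        contigs, bed = _simulate.assemble_genome(succession,
                                                 spacer_mean=c.spacer_mean,
                                                 seed=c.seed + 1)
        gold = _simulate.derive_gold_standards(
            succession, tail_length=c.gold_tail_length,
            noise_rate=c.gold_noise_rate, seed=c.seed + 2)
        full_len = max(len(t.progenitor_seq) for t in succession)
        library = {
            f"lib_{t.subfamily_id}": s for t, s in zip(
                succession,
                _simulate.derive_gold_standards(
                    succession, tail_length=full_len,
                    noise_rate=c.library_noise_rate,
                    seed=c.seed + 3).values())
        }

        seqio.write_fasta(out / "genome.fasta", contigs)
        bed.to_csv(out / "truth.tsv", sep="\t", index=False)
        seqio.write_fasta(out / "gold_standards.fasta", gold)
        seqio.write_fasta(out / "library.fasta", library)
        seqio.write_fasta(out / "progenitors.fasta",
                          {t.subfamily_id: t.progenitor_seq
                           for t in succession})
        (out / "succession.nwk").write_text(succession[-1].genealogy + "\n")
        # reference proteins: the youngest subfamily's ORF products (the
        # analog of the curated L1HS ORF1p/ORF2p entries)
        young = succession[-1]
        ref = {}
        for orf_id in ("ORF1", "ORF2"):
            a, b = young.spec.orf_span(orf_id)
            ref[orf_id] = seqio.translate(young.progenitor_seq[a:b])[:-1]
        seqio.write_fasta(out / "reference_proteins.fasta", ref)
        copies = {c2.copy_id: c2.sequence
                  for t in succession for c2 in t.copies}
        seqio.write_fasta(out / "copies.fasta", copies)

        if c.kzfp_enabled:
            peaks, kz_truth = _simulate.simulate_kzfp_data(
                succession, contigs, bed, _simulate.DEFAULT_KZFP_ID,
                background_peaks=c.n_background_peaks, seed=c.seed + 4)
            peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
            kz_truth.to_csv(out / "kzfp_truth.tsv", sep="\t", index=False)
        log.info("simulate: %d subfamilies, %d copies, genome %d bp",
                 len(succession), len(copies),
                 sum(len(s) for s in contigs.values()))

    def scan(self) -> None:
        c = self.cfg
        out = self._dir("scan")
        sim = self._dir("simulate")
        contigs = seqio.read_fasta(sim / "genome.fasta")
        library = seqio.read_fasta(sim / "library.fasta")
        models = {k.replace("lib_", ""): v for k, v in library.items()}
        cutoffs = {m: (c.e_cutoff_old if m in set(c.old_classes)
                       else c.e_cutoff_young) for m in models}
        ap = _align.AlignmentParams()
        calibration = _annotate.calibrate_scoring(ap.match, ap.mismatch)
        raw = _annotate.scan_genome(contigs, models, cutoffs,
                                    calibration=calibration, params=ap)
        resolved = _annotate.join_and_group_hits(
            raw, join_gap=c.join_gap, overlap_min=c.overlap_min,
            overlap_min_old=c.overlap_min_old,
            old_classes=set(c.old_classes), seed=c.seed,
            calibration=calibration)
        _annotate.hits_to_dataframe(resolved).to_csv(
            out / "hits.tsv", sep="\t", index=False)
        log.info("scan: %d raw hits -> %d resolved loci", len(raw),
                 len(resolved))

    def _load_hits(self) -> pd.DataFrame:
        return pd.read_csv(self._dir("scan") / "hits.tsv", sep="\t")

    def _subfamily_hit_seqs(self, subfamily: str) -> tuple[list[str], list[str]]:
        """Top (longest) hit sequences >= min_hit_length for one subfamily."""
        c = self.cfg
        contigs = seqio.read_fasta(self._dir("simulate") / "genome.fasta")
        hits = self._load_hits()
        hits = hits[hits["name"] == subfamily].copy()
        hits["length"] = hits["end"] - hits["start"]
        hits = hits[hits["length"] >= c.min_hit_length]
        hits = hits.sort_values("length", ascending=False).head(c.max_hits)
        seqs, ids = [], []
        for _, row in hits.iterrows():
            seq = contigs[row["chrom"]][row["start"]:row["end"]]
            if row["strand"] == "-":
                seq = seqio.revcomp(seq)
            seqs.append(seq)
            ids.append(f"{row['chrom']}:{row['start']}-{row['end']}"
                       f"({row['strand']})")
        return seqs, ids

    def reconstruct(self) -> None:
        c = self.cfg
        out = self._dir("reconstruct")
        subfams = sorted(self._load_hits()["name"].unique())
        records = {}
        rows = []
        for sub in subfams:
            seqs, ids = self._subfamily_hit_seqs(sub)
            log.info("reconstruct %s: %d input sequences >= %d bp", sub,
                     len(seqs), c.min_hit_length)
            if len(seqs) < 3:
                log.warning("reconstruct %s: too few sequences, skipped", sub)
                continue
            for method, rec in reconstruct_both_indel_methods(
                    seqs, ids, max_gap_frac=c.max_gap_frac).items():
                name = f"{sub}|g1|{method}"
                records[name] = rec.root_sequence
                rows.append({"subfamily": sub, "genome": "g1",
                             "indel_method": method,
                             "length": len(rec.root_sequence),
                             "mean_max_posterior": rec.mean_max_posterior,
                             "n_inputs": len(seqs)})
        seqio.write_fasta(out / "candidates.fasta", records)
        pd.DataFrame(rows).to_csv(out / "candidates.tsv", sep="\t",
                                  index=False)

    def select(self) -> None:
        out = self._dir("select")
        cands_fa = seqio.read_fasta(self._dir("reconstruct") / "candidates.fasta")
        gold = seqio.read_fasta(self._dir("simulate") / "gold_standards.fasta")
        chosen = {}
        rows = []
        for sub in sorted({k.split("|")[0] for k in cands_fa}):
            cands = []
            for name, seq in cands_fa.items():
                s, genome, method = name.split("|")
                if s != sub:
                    continue
                cands.append(_selection.CandidateProgenitor(
                    subfamily=sub, source_genome=genome,
                    indel_method=method, sequence=seq, age_rank=0))
            standards = {k: v for k, v in gold.items()
                         if k == f"gold_{sub}"}
            _selection.score_candidates(cands, standards)
            outcome = _selection.select_best_candidate(cands)
            chosen[sub] = outcome.chosen
            tbl = _selection.candidates_table(cands, outcome.chosen)
            rows.append(tbl)
            log.info("select %s: %s (identity %.2f%%, %d bp)", sub,
                     outcome.chosen.candidate_id,
                     outcome.chosen.best_identity, outcome.chosen.length)
        seqio.write_fasta(out / "best.fasta",
                          {s: c.sequence for s, c in chosen.items()})
        pd.concat(rows, ignore_index=True).to_csv(
            out / "selection.tsv", sep="\t", index=False)
        meta = {s: {"source_genome": c.source_genome,
                    "indel_method": c.indel_method,
                    "best_identity": c.best_identity}
                for s, c in chosen.items()}
        (out / "best.json").write_text(json.dumps(meta, indent=2))

    def refine_orfs(self) -> None:
        out = self._dir("refine_orfs")
        ref = seqio.read_fasta(self._dir("simulate") / "reference_proteins.fasta")
        subfams = sorted(self._load_hits()["name"].unique())
        best = {}
        rows = []
        for sub in subfams:
            seqs, ids = self._subfamily_hit_seqs(sub)
            for orf_id, target in (("ORF1", _orfs.ORF1_TARGET_AA),
                                   ("ORF2", _orfs.ORF2_TARGET_AA)):
                profiles = _orfs.orf_profiles(orf_id)
                regions = []
                for s in seqs:
                    span = _orfs.locate_orf_region(s, ref[orf_id])
                    if span is not None:
                        regions.append(s[span[0]:span[1]])
                if len(regions) < 3:
                    log.warning("refine-orfs %s %s: too few regions", sub,
                                orf_id)
                    continue
                cands = []
                for method in ("ml", "parsimony"):
                    cand = _orfs.reconstruct_orf(
                        regions, profiles=profiles, subfamily=sub,
                        source_genome="g1", indel_method=method,
                        ref_protein=ref[orf_id])
                    cand.orf_id = orf_id
                    cands.append(cand)
                    rows.append({
                        "subfamily": sub, "orf_id": orf_id,
                        "indel_method": method,
                        "n_domains": cand.n_domains,
                        "n_frames_used": cand.n_frames_used,
                        "n_premature_stops": cand.n_premature_stops,
                        "aa_length": cand.aa_length})
                winner, _audit = _orfs.select_best_orf(cands, target)
                best[f"{sub}|{orf_id}"] = winner
                log.info("refine-orfs %s %s: %d domains, %d stops", sub,
                         orf_id, winner.n_domains, winner.n_premature_stops)
        seqio.write_fasta(out / "best_orfs.fasta",
                          {k: v.nt_sequence for k, v in best.items()})
        meta = {k: {"indel_method": v.indel_method, "n_domains": v.n_domains,
                    "source_genome": v.source_genome}
                for k, v in best.items()}
        (out / "best_orfs.json").write_text(json.dumps(meta, indent=2))
        pd.DataFrame(rows).to_csv(out / "orf_candidates.tsv", sep="\t",
                                  index=False)

    def composite(self) -> None:
        out = self._dir("composite")
        ref = seqio.read_fasta(self._dir("simulate") / "reference_proteins.fasta")
        best_fl = seqio.read_fasta(self._dir("select") / "best.fasta")
        meta = json.loads((self._dir("select") / "best.json").read_text())
        orfs_fa = seqio.read_fasta(self._dir("refine_orfs") / "best_orfs.fasta")
        orfs_meta = json.loads(
            (self._dir("refine_orfs") / "best_orfs.json").read_text())
        composites = {}
        seg_rows = []
        for sub, backbone_seq in sorted(best_fl.items()):
            backbone = _selection.CandidateProgenitor(
                subfamily=sub, source_genome=meta[sub]["source_genome"],
                indel_method=meta[sub]["indel_method"], sequence=backbone_seq)
            orf_cands = {}
            for orf_id in ("ORF1", "ORF2"):
                key = f"{sub}|{orf_id}"
                if key in orfs_fa:
                    om = orfs_meta[key]
                    orf_cands[orf_id] = _orfs.OrfCandidate(
                        subfamily=sub, source_genome=om["source_genome"],
                        orf_id=orf_id, nt_sequence=orfs_fa[key],
                        indel_method=om["indel_method"])
                else:
                    orf_cands[orf_id] = None
            cs = _orfs.assemble_composite(backbone, orf_cands["ORF1"],
                                          orf_cands["ORF2"],
                                          ref["ORF1"], ref["ORF2"])
            composites[sub] = cs
            for s, e, prov in cs.segments:
                seg_rows.append({"subfamily": sub, "seg_start": s,
                                 "seg_end": e, "provenance": prov})
        seqio.write_fasta(out / "composites.fasta",
                          {s: c.sequence for s, c in composites.items()})
        pd.DataFrame(seg_rows).to_csv(out / "provenance.tsv", sep="\t",
                                      index=False)

    def kzfp(self) -> None:
        c = self.cfg
        if not c.kzfp_enabled:
            return
        out = self._dir("kzfp")
        sim = self._dir("simulate")
        composites = seqio.read_fasta(self._dir("composite") / "composites.fasta")
        pwm = _kzfp.pfm_to_pwm(_simulate.default_kzfp_pfm(),
                               motif_id=_simulate.DEFAULT_KZFP_ID)
        hits = _kzfp.scan_pwm(composites, pwm)
        _kzfp.hits_to_bed(hits, pwm).to_csv(out / "motif_hits.tsv", sep="\t",
                                            index=False)

        peaks = pd.read_csv(sim / "peaks.tsv", sep="\t")
        contigs = seqio.read_fasta(sim / "genome.fasta")
        lengths = {k: len(v) for k, v in contigs.items()}
        control = _kzfp.shuffle_peaks(peaks, lengths, seed=c.seed + 5)
        loci = self._load_hits()
        calls = []
        for sub in sorted(composites):
            sub_loci = loci[loci["name"] == sub]
            call = _kzfp.test_subfamily_enrichment(
                peaks, sub_loci, control, kzfp_id=pwm.motif_id,
                subfamily=sub)
            calls.append(call)
            log.info("kzfp %s: %d/%d top peaks, p=%.3g, enriched=%s", sub,
                     call.n_top_peaks_overlapping, _kzfp.ENRICH_TOP_N,
                     call.fisher_p, call.enriched)
        _kzfp.enrichment_table(calls).to_csv(out / "enrichment.tsv",
                                             sep="\t", index=False)

    def annotate(self) -> None:
        c = self.cfg
        out = self._dir("annotate")
        contigs = seqio.read_fasta(self._dir("simulate") / "genome.fasta")
        models = seqio.read_fasta(self._dir("composite") / "composites.fasta")
        cutoffs = {m: (c.e_cutoff_old if m in set(c.old_classes)
                       else c.e_cutoff_young) for m in models}
        ap = _align.AlignmentParams()
        calibration = _annotate.calibrate_scoring(ap.match, ap.mismatch)
        raw = _annotate.scan_genome(contigs, models, cutoffs,
                                    calibration=calibration, params=ap)
        resolved = _annotate.join_and_group_hits(
            raw, join_gap=c.join_gap, overlap_min=c.overlap_min,
            overlap_min_old=c.overlap_min_old,
            old_classes=set(c.old_classes), seed=c.seed,
            calibration=calibration)
        _annotate.hits_to_dataframe(resolved).to_csv(
            out / "annotation.tsv", sep="\t", index=False)
        log.info("annotate: %d raw -> %d resolved", len(raw), len(resolved))

    def evaluate(self) -> None:
        out = self._dir("evaluate")
        sim = self._dir("simulate")
        truth_prog = seqio.read_fasta(sim / "progenitors.fasta")
        composites = seqio.read_fasta(self._dir("composite") / "composites.fasta")

        metrics: dict = {"composite_identity_pct": {}}
        for sub, seq in sorted(composites.items()):
            ident = _selection.identity_to_standard(seq, truth_prog[sub])
            metrics["composite_identity_pct"][sub] = round(ident, 3)

        # phylogeny consistency of the composites vs the simulated succession
        if len(composites) >= 3:
            ids = sorted(composites)
            msa = _align.progressive_msa([composites[i] for i in ids], ids=ids)
            tree = _phylo.neighbor_joining(_phylo.k2p_distance_matrix(msa))
            from skbio import TreeNode
            import io as _io
            truth_tree = TreeNode.read(
                _io.StringIO((sim / "succession.nwk").read_text()))
            # truth tree spans all subfamilies; prune to reconstructed ones
            truth_tree = truth_tree.shear(ids)
            metrics["composite_tree_rf"] = _phylo.robinson_foulds(
                tree, truth_tree)

        ann = pd.read_csv(self._dir("annotate") / "annotation.tsv", sep="\t")
        hits = [
            _annotate.AnnotationHit(
                contig=r["chrom"], start=r["start"], end=r["end"],
                strand=r["strand"], subfamily=r["name"],
                raw_score=r["score"], e_value=r["evalue"])
            for _, r in ann.iterrows()]
        truth_bed = pd.read_csv(sim / "truth.tsv", sep="\t")
        metrics["annotation_base_accuracy"] = round(
            _annotate.base_accuracy(hits, truth_bed), 4)

        if self.cfg.kzfp_enabled:
            kz_truth = pd.read_csv(sim / "kzfp_truth.tsv", sep="\t")
            calls = pd.read_csv(self._dir("kzfp") / "enrichment.tsv", sep="\t")
            merged = kz_truth.merge(calls, on="subfamily", how="inner")
            agree = (merged["bound"] == merged["enriched"]).mean()
            metrics["kzfp_enrichment_accuracy"] = round(float(agree), 4)
            # motif presence on the composites vs planted truth
            pwm = _kzfp.pfm_to_pwm(_simulate.default_kzfp_pfm(),
                                   motif_id=_simulate.DEFAULT_KZFP_ID)
            hits = _kzfp.scan_pwm(composites, pwm)
            with_hit = {h.sequence_id for h in hits}
            ok = 0
            for _, row in kz_truth.iterrows():
                if row["subfamily"] in composites:
                    ok += int((row["subfamily"] in with_hit) == row["bound"])
            metrics["kzfp_motif_accuracy"] = round(
                ok / max(1, len(composites)), 4)

        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        log.info("evaluate: %s", json.dumps(metrics))

    # -- driver ------------------------------------------------------------

    def run_stage(self, stage: str) -> None:
        name = stage.replace("-", "_")
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        getattr(self, name)()

    def run_all(self) -> dict:
        for stage in STAGES:
            log.info("=== stage %s ===", stage)
            self.run_stage(stage)
        return self.write_manifest()

    def write_manifest(self) -> dict:
        artifacts = {}
        for path in sorted(self.root.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                artifacts[str(path.relative_to(self.root))] = \
                    seqio.sha256_file(path)
        manifest = {"seed": self.cfg.seed, "artifacts": artifacts}
        (self.root / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        return manifest


def reconstruct_both_indel_methods(seqs: list[str], ids: list[str],
                                   max_gap_frac: float = 0.9,
                                   params: "_align.AlignmentParams | None" = None
                                   ) -> dict[str, _phylo.AncestralReconstruction]:
    """MSA once, tree and model once, then one reconstruction per indel
    method (ML and parsimony) — the two candidate roots per alignment."""
    import numpy as _np

    msa = _align.progressive_msa(seqs, params=params, ids=ids)
    # share the filtered alignment, tree and fitted model across methods
    codes = msa.codes()
    kept = _np.where((codes == 4).mean(axis=0) <= max_gap_frac)[0]
    sub = _align.Msa(ids=list(msa.ids),
                     rows=["".join(r[c] for c in kept) for r in msa.rows])
    # cap saturated/disjoint pairs: truncated hits of one subfamily can
    # cover non-overlapping alignment regions
    tree = _phylo.neighbor_joining(
        _phylo.k2p_distance_matrix(sub, on_saturation="cap"),
        midpoint_root=True)
    model = _phylo.fit_gtr(sub, tree)
    out = {}
    for method in ("ml", "parsimony"):
        rec = _phylo.marginal_root_reconstruction(
            sub, tree=tree, model=model, indel_method=method,
            max_gap_frac=1.0)
        out[method.upper() if method == "ml" else method] = rec
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the output manifest."""
    return Pipeline(config).run_all()


def progenitor_recovery_experiment(seed: int = 1, n_copies: int = 60,
                                   divergence: float = 0.08,
                                   truncation_prob: float = 0.7,
                                   min_length: int = 3000,
                                   indel_method: str = "ml") -> dict:
    """Core-premise check: ancestral reconstruction beats every single copy.

    Simulates one 6.5 kb progenitor and ``n_copies`` degraded copies,
    reconstructs the root from the >=3 kb copies (the pipeline's own filter),
    and scores identity to the true progenitor over its 3' half — the region
    where every gold standard lives — for both the reconstruction and the
    best individual copy.
    """
    spec = _simulate.ProgenitorSpec()
    root = _simulate.simulate_progenitor(spec, seed=seed)
    params = _simulate.EvolutionParams(
        copies_per_subfamily=n_copies, divergence_per_copy=divergence,
        truncation_prob=truncation_prob, seed=seed)
    truth = _simulate.generate_copies(root, params)
    usable = [c.sequence for c in truth.copies if len(c.sequence) >= min_length]
    usable = sorted(usable, key=len, reverse=True)[:100]
    msa = _align.progressive_msa(usable,
                                 ids=[f"c{i}" for i in range(len(usable))])
    rec = _phylo.marginal_root_reconstruction(msa, indel_method=indel_method)

    half = len(root.progenitor_seq) // 2
    tail_truth = root.progenitor_seq[half:]
    window = len(tail_truth) + 200  # 3'-terminal slice covering the tail

    def tail_identity(seq: str) -> float:
        return _selection.identity_to_standard(seq[-window:], tail_truth)

    root_ident = tail_identity(rec.root_sequence)
    copy_idents = [tail_identity(c) for c in usable]
    return {
        "n_inputs": len(usable),
        "root_identity_3p": root_ident,
        "best_copy_identity_3p": max(copy_idents),
        "mean_max_posterior": rec.mean_max_posterior,
        "root_length": len(rec.root_sequence),
    }


def frameshift_repair_experiment(seed: int = 1, n_copies: int = 20,
                                 frameshift_fraction: float = 0.3,
                                 divergence: float = 0.05) -> dict:
    """Codon-aware vs nucleotide-only reconstruction of a frameshifted ORF set.

    A clean ancestral ORF1-sized coding sequence spawns ``n_copies``
    substitution-diverged copies; ``frameshift_fraction`` of them receive a
    single 1-nt indel. Both reconstruction routes run on the same inputs,
    and each root's frameshift count is measured against the ancestral
    protein with the codon aligner. A homologous (not ancestral) protein
    from a sibling sequence serves as the codon-alignment scaffold, as in
    the full pipeline.
    """
    rng = np.random.default_rng(seed)
    spec = _simulate.ProgenitorSpec()
    root = _simulate.simulate_progenitor(spec, seed=seed)
    a, b = spec.orf_span("ORF1")
    true_orf = root.progenitor_seq[a:b]
    true_aa = seqio.translate(true_orf)[:-1]
    params = _simulate.EvolutionParams(seed=seed)

    # homologous reference protein: a coding-intact sibling of the truth
    sib = _simulate.evolve_succession(root, 2, params)[1]
    ref_aa = seqio.translate(sib.progenitor_seq[a:b])[:-1]

    copies = []
    n_fs = max(1, round(frameshift_fraction * n_copies))
    for i in range(n_copies):
        seq, _ = _simulate._simulate_substitutions(true_orf, divergence,
                                                   params, rng)
        if i < n_fs:
            pos = int(rng.integers(30, len(seq) - 30))
            if rng.random() < 0.5:
                seq = seq[:pos] + "ACGT"[rng.integers(0, 4)] + seq[pos:]
            else:
                seq = seq[:pos] + seq[pos + 1:]
        copies.append(seq)

    ids = [f"c{i}" for i in range(n_copies)]
    codon_msa = _align.codon_aware_msa(copies, ids=ids, ref_protein=ref_aa)
    codon_rec = _phylo.marginal_root_reconstruction(codon_msa)
    nt_msa = _align.progressive_msa(copies, ids=ids)
    nt_rec = _phylo.marginal_root_reconstruction(nt_msa)

    def n_frameshifts(seq: str) -> int:
        # measure true frame disruptions: the reduced stop penalty stops the
        # measuring aligner from frameshifting around point-error stops
        _, nfs, _ = _align.codon_pairwise_protein(
            seq, true_aa, stop_cost=_align.AlignmentParams().stop_cost_degraded)
        return nfs

    codon_root = codon_rec.root_sequence
    return {
        "fs_codon": n_frameshifts(codon_root),
        "fs_nt": n_frameshifts(nt_rec.root_sequence),
        "codon_stop_free": _align.count_stops(codon_root) == 0,
        "codon_root_len": len(codon_root),
        "nt_root_len": len(nt_rec.root_sequence),
    }


def kzfp_truth_experiment(seed: int = 1, n_subfamilies: int = 5,
                          copies_per_subfamily: int = 60,
                          spacer_mean: int = 40000,
                          loss_at: int = 2,
                          background_peaks: int = 50,
                          site_offset: int = 6200) -> pd.DataFrame:
    """Planted gain/loss recovery across a subfamily succession.

    Simulates a succession carrying one KZFP site with a loss event, builds
    the genomic copy set and ChIP-style peaks (large intergenic spacers give
    the hg38-like regime where subfamily loci are a small genome fraction
    and the top peaks are dominated by genuine binding), then recovers the
    per-subfamily truth two ways: PWM motif presence on the true progenitor
    sequences and dual-criterion peak enrichment against shuffled controls.

    Returns a DataFrame with columns subfamily, bound (truth), motif_hit,
    enriched, fisher_p, n_overlap.
    """
    spec = _simulate.ProgenitorSpec(
        kzfp_sites=[(_simulate.DEFAULT_KZFP_ID, site_offset, True)])
    root = _simulate.simulate_progenitor(spec, seed=seed)
    params = _simulate.EvolutionParams(
        copies_per_subfamily=copies_per_subfamily, seed=seed)
    succession = _simulate.evolve_succession(
        root, n_subfamilies, params,
        site_events=[(loss_at, _simulate.DEFAULT_KZFP_ID, "loss")])
    succession = [_simulate.generate_copies(t, params) for t in succession]
    contigs, bed = _simulate.assemble_genome(succession,
                                             spacer_mean=spacer_mean,
                                             seed=seed + 1)
    peaks, truth = _simulate.simulate_kzfp_data(
        succession, contigs, bed, _simulate.DEFAULT_KZFP_ID,
        background_peaks=background_peaks, seed=seed + 2)

    pwm = _kzfp.pfm_to_pwm(_simulate.default_kzfp_pfm(),
                           motif_id=_simulate.DEFAULT_KZFP_ID)
    progenitors = {t.subfamily_id: t.progenitor_seq for t in succession}
    motif_hits = {h.sequence_id for h in _kzfp.scan_pwm(progenitors, pwm)}

    lengths = {k: len(v) for k, v in contigs.items()}
    control = _kzfp.shuffle_peaks(peaks, lengths, seed=seed + 3)
    rows = []
    for t in succession:
        loci = bed[bed["subfamily"] == t.subfamily_id].rename(
            columns={"subfamily": "_sub"})
        call = _kzfp.test_subfamily_enrichment(
            peaks, loci, control, kzfp_id=pwm.motif_id,
            subfamily=t.subfamily_id)
        bound = bool(truth[truth["subfamily"] == t.subfamily_id]
                     ["bound"].iloc[0])
        rows.append({"subfamily": t.subfamily_id, "bound": bound,
                     "motif_hit": t.subfamily_id in motif_hits,
                     "enriched": call.enriched,
                     "fisher_p": call.fisher_p,
                     "n_overlap": call.n_top_peaks_overlapping})
    return pd.DataFrame(rows)
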