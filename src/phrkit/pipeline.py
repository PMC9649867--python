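"""Orchestration of the analysis stages with a reproducibility manifest.

Two bundles mirror the study's two analysis arms: the homolog screen
(BLAST filter -> redundancy clustering -> residue-rule conservation ->
classification and logo data) and the operon arm (feature annotation +
in-silico PCR + qPCR relative expression).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import conservation, homology, operon, qpcr
from .records import Msa

log = logging.getLogger("phrkit")
if not log.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    evalue_max: float = 1e-3
    identity_min: float = 30.0
    redundancy_threshold: float = 0.85
    min_coverage: float = 0.7
    max_gap: int = 50
    sd_window: tuple = (4, 13)
    promoter_min_score: int = 8
    pcr_max_mismatch: int = 0
    pcr_max_product: int = 5000
    reference_genes: tuple = ("PPC", "RNPB")
    control_condition: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.redundancy_threshold <= 1:
            raise ValueError("redundancy_threshold must be in (0, 1]")
        if self.evalue_max <= 0 or not 0 <= self.identity_min <= 100:
            raise ValueError("thresholds out of documented range")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir: Path, config, inputs: dict) -> None:
    import phrkit
    manifest = {
        "phrkit_version": phrkit.__version__,
        "config": asdict(config) if hasattr(config, "__dataclass_fields__") else dict(config),
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in inputs.items() if p is not None and Path(p).exists()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def run_homolog_pipeline(config: PipelineConfig, blast_tsv, fasta, msa_fasta,
                         ref_id: str, out_dir, clades: dict | None = None) -> dict:
    """Filter hits, cluster redundancy, score conservation, classify homologs.

    Sequence ids present in the FASTA but absent from the MSA (or vice
    versa) are rejected, listing the offenders. Writes filtered hit, cluster,
    conservation, logo and classification tables plus a manifest; returns the
    bundle as a dict of DataFrames / counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    hits = homology.read_blast_tabular(blast_tsv) if blast_tsv else []
    kept = homology.filter_blast_hits(hits, config.evalue_max, config.identity_min)
    log.info("screen: %d hits in, %d pass E<%g and id>%g", len(hits), len(kept),
             config.evalue_max, config.identity_min)

    records = homology.read_fasta(fasta)
    msa = conservation.read_alignment(msa_fasta)
    fasta_ids, msa_ids = {r.id for r in records}, set(msa.ids)
    if fasta_ids.symmetric_difference(msa_ids) - {ref_id}:
        offenders = sorted(fasta_ids.symmetric_difference(msa_ids) - {ref_id})
        raise ValueError(f"FASTA/MSA id mismatch: {offenders}")

    kept_ids = {h.subject_id for h in kept}
    if kept_ids:
        records = [r for r in records if r.id in kept_ids or r.id == ref_id]
        keep = kept_ids | {ref_id}
        msa = Msa([i for i in msa.ids if i in keep],
                  [row for i, row in zip(msa.ids, msa.rows) if i in keep])
    elif hits:
        log.warning("screen: no hits pass the thresholds; empty bundle")

    clusters = homology.cluster_redundant(records, config.redundancy_threshold)
    log.info("cluster: %d records -> %d clusters at >%.0f%% identity",
             len(records), len(clusters), config.redundancy_threshold * 100)

    report = conservation.apply_residue_rules(msa, ref_id)
    labels, counts = conservation.classify_homologs(report, clades)
    # the reference trivially passes its own rules; count screened sequences only
    if labels.get(ref_id) == "true_homolog":
        counts["all"] -= 1
    labels.pop(ref_id, None)
    log.info("conserve: %d/%d screened sequences pass all %d rules",
             counts["all"], len(labels), len(report.rules))
    logo = conservation.logo_table(msa)

    pd.DataFrame([h.__dict__ for h in kept]).to_csv(out_dir / "filtered_hits.tsv",
                                                    sep="\t", index=False)
    homology.write_cluster_report(clusters, out_dir / "clusters.tsv")
    report.to_frame().to_csv(out_dir / "conservation.tsv", sep="\t", index=False)
    logo.to_csv(out_dir / "logo_data.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(labels.items()), columns=["sequence", "label"]).to_csv(
        out_dir / "classification.tsv", sep="\t", index=False)
    write_manifest(out_dir, config, {"blast": blast_tsv, "fasta": fasta, "msa": msa_fasta})
    return {"filtered_hits": kept, "clusters": clusters, "report": report,
            "labels": labels, "counts": counts, "logo": logo}


def run_operon_pipeline(config: PipelineConfig, fasta, primers_tsv, ct_tsv, out_dir) -> dict:
    """Annotate the operon sequence and compute relative expression.

    Writes GFF3 plus overlap/SD/promoter/TF/amplicon tables and the
    expression report; returns the bundle.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from Bio import SeqIO
    seqs = list(SeqIO.parse(str(fasta), "fasta"))
    seq = str(seqs[0].seq).upper()
    seqid = seqs[0].id

    orfs = operon.find_orfs(seq)
    if not orfs:
        log.warning("operon: no ORFs above the length floor")
    operons = operon.predict_operons(orfs, config.max_gap)
    # annotate the group carrying the longest gene (the photolyase operon)
    op_feats = (max(operons, key=lambda g: (max(f.length for f in g),
                                            sum(f.length for f in g)))
                if operons else orfs)
    overlaps = operon.detect_overlaps(op_feats, seq)
    sd_hits = operon.find_sd_motifs(seq, op_feats, window=config.sd_window)
    # promoter search region: upstream of the operon in transcription
    # direction; minus-strand operons are scanned on the reverse complement
    # and hits mirrored back to forward coordinates
    n = len(seq)
    minus = bool(op_feats) and op_feats[0].strand == "-"
    scan_seq = operon.revcomp(seq) if minus else seq
    if minus:
        win = (1, n - max(f.end for f in op_feats))
    elif op_feats:
        win = (1, min(f.start for f in op_feats) - 1)
    else:
        win = (1, n)
    promoters = (operon.scan_promoter(scan_seq, win, min_score=config.promoter_min_score)
                 if 1 <= win[0] <= win[1] <= n else [])
    if minus:
        promoters = [operon.PromoterHit(h.minus35, n - (h.minus35_start + len(h.minus35) - 1) + 1,
                                        h.minus10, n - (h.minus10_start + len(h.minus10) - 1) + 1,
                                        h.spacing, h.score)
                     for h in promoters]
    tf_hits = operon.scan_tf_sites(seq)
    log.info("operon: %d ORFs, %d operon(s), %d overlap(s), %d SD hit(s)",
             len(orfs), len(operons), len(overlaps), len(sd_hits))

    amplicons = []
    if primers_tsv:
        primer_df = pd.read_csv(primers_tsv, sep="\t")
        for row in primer_df.itertuples():
            pair = operon.PrimerPair(str(row.name), str(row.forward), str(row.reverse))
            amplicons.extend(operon.in_silico_pcr(seq, pair, config.pcr_max_mismatch,
                                                  config.pcr_max_product))
        log.info("pcr: %d amplicon(s)", len(amplicons))

    expression = None
    if ct_tsv:
        ct = qpcr.read_ct_table(ct_tsv)
        expression = qpcr.expression_table(ct, config.reference_genes,
                                           config.control_condition)
        log.info("qpcr: %d gene x condition rows", len(expression))

    (out_dir / "features.gff3").write_text(operon.features_to_gff3(orfs, seqid))
    for name, objs in (("overlaps", overlaps), ("sd_hits", sd_hits),
                       ("promoters", promoters), ("tf_sites", tf_hits),
                       ("amplicons", amplicons)):
        pd.DataFrame([o.__dict__ for o in objs]).to_csv(out_dir / f"{name}.tsv",
                                                        sep="\t", index=False)
    if expression is not None:
        expression.to_csv(out_dir / "expression.tsv", sep="\t", index=False)
    write_manifest(out_dir, config, {"fasta": fasta, "primers": primers_tsv, "ct": ct_tsv})
    return {"orfs": orfs, "operons": operons, "overlaps": overlaps, "sd_hits": sd_hits,
            "promoters": promoters, "tf_sites": tf_hits, "amplicons": amplicons,
            "expression": expression}
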