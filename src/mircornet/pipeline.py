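"""End-to-end orchestration: QC -> DE -> targets -> PCIT networks ->
connectivity/rewiring -> duplex MFE -> enrichment.

The pipeline runs either on user-supplied files (counts, sample sheet,
FASTA, TargetScan table, GMT) or in synthetic mode, where all inputs are
generated with planted truth and written alongside the outputs. All stage
thresholds default to the printed study values (p 0.05, |log2FC| 0.5,
context++ -0.4, |r| 0.6, z 1.96, mfe -20 kcal/mol, kappa 0.4, CPM 1 in
50% of samples). One seed drives every source of randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mircornet import connectivity as conn
from mircornet import io, qc
from mircornet.containers import CountMatrix, NormalizedMatrix
from mircornet.de import classify_demis, de_table, nb_wald_test, size_factors, volcano_table
from mircornet.enrich import enrichment_table, ora, read_gmt, write_gmt
from mircornet.mfe import DuplexRecord, duplex_mfe, duplex_table, gene_average_mfe
from mircornet.pcit import build_group_network
from mircornet.synthetic import (
    SyntheticConfig,
    generate_counts,
    generate_pathways,
    generate_sequences,
    generate_targetscan_table,
)
from mircornet.targets import intersect_expressed, load_targetscan

logger = logging.getLogger(__name__)

GROUPS = ("FH", "SFH")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # inputs (ignored in synthetic mode)
    mirna_counts: str | None = None
    mrna_counts: str | None = None
    sample_sheet: str | None = None
    mirna_fasta: str | None = None
    utr_fasta: str | None = None
    targetscan_table: str | None = None
    gmt: str | None = None
    # stage thresholds (defaults = the study's printed values)
    p_thresh: float = 0.05
    fc_thresh: float = 0.5
    context_thresh: float = -0.4
    r_min: float = 0.6
    z_crit: float = 1.96
    mfe_cutoff: float = -20.0
    kappa_min: float = 0.4
    min_cpm: float = 1.0
    min_frac: float = 0.5
    #: expression scale for network correlations: "log2" or "raw"
    cpm_scale: str = "log2"
    # execution
    synthetic: bool = False
    mfe_all_pairs: bool = False
    seed: int = 0
    output_dir: str = "mircornet_out"
    synthetic_overrides: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir")
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _tx_to_gene(transcript_id: str) -> str:
    """Gene id from a transcript id (strip a trailing .N suffix if present)."""
    head, _, tail = transcript_id.rpartition(".")
    return head if head and tail.lstrip("t").isdigit() else transcript_id


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def _write_sif(edges, path: Path) -> None:
    lines = [
        "\t".join(
            [
                e.node_a,
                "pos" if e.r > 0 else "neg",
                e.node_b,
                f"{e.r:.6g}",
                e.edge_class,
                e.group,
            ]
        )
        for e in edges
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def edges_table(edges) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.node_a, e.node_b, e.r, e.group, e.edge_class, e.pcit_significant, e.p_value)
            for e in edges
        ],
        columns=["node_a", "node_b", "r", "group", "edge_class", "pcit_significant", "p"],
    )


def summarize_pairs(
    de_records,
    predictions,
    networks: dict,
    mfe_records: list[DuplexRecord],
) -> pd.DataFrame:
    """Integrated (miRNA, gene) table over DEMIs x predicted expressed targets.

    One row per pair; per-group correlation and PCIT flags where the pair
    is an edge; gene-average mfe and its pass flag where computed. The
    headline pairs are predicted AND negatively correlated in a group AND
    past the mfe cutoff.
    """
    de_by_id = {r.feature_id: r for r in de_records}
    demis = {r.feature_id for r in de_records if r.status != "not_significant"}
    orphans = sorted({p.mirna_id for p in predictions} - set(de_by_id))
    if orphans:
        raise ValueError(f"predictions for miRNAs absent from DE results: {orphans}")

    edge_lookup = {}
    for group, edges in networks.items():
        for e in edges:
            edge_lookup[(group, e.node_a, e.node_b)] = e
    mfe_by_pair = {}
    for rec in mfe_records:
        mfe_by_pair[(rec.mirna_id, rec.gene_id)] = rec

    rows = []
    for p in sorted(predictions, key=lambda p: (p.mirna_id, p.gene_id)):
        if p.mirna_id not in demis:
            continue
        row = {
            "miRNA": p.mirna_id,
            "gene": p.gene_id,
            "demi_status": de_by_id[p.mirna_id].status,
            "context_score": p.cumulative_context_score,
            "predicted": True,
        }
        negative_any = False
        for group in GROUPS:
            key = (group, *sorted((p.mirna_id, p.gene_id)))
            e = edge_lookup.get(key)
            row[f"r_{group.lower()}"] = e.r if e else np.nan
            row[f"pcit_{group.lower()}"] = bool(e)
            negative_any |= bool(e and e.r < 0)
        rec = mfe_by_pair.get((p.mirna_id, p.gene_id))
        row["gene_avg_mfe"] = rec.gene_avg_mfe if rec else np.nan
        row["mfe_pass"] = bool(rec and rec.passes_cutoff)
        row["headline"] = bool(negative_any and rec and rec.passes_cutoff)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("mircornet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def record(stage: str, name: str, df: pd.DataFrame | None = None, path: Path | None = None):
        entry = manifest["stages"].setdefault(stage, {})
        entry[name] = {
            "file": str(path.relative_to(outdir)) if path else None,
            "rows": int(len(df)) if df is not None else None,
        }

    try:
        # ---------------- inputs -------------------------------------
        if config.synthetic:
            syn = SyntheticConfig(seed=config.seed, **config.synthetic_overrides)
            inputs = outdir / "inputs"
            inputs.mkdir(exist_ok=True)
            mir_cm, gene_cm, truth = _stage("synth")(generate_counts)(syn)
            mirna_seqs, utr_seqs = _stage("synth")(generate_sequences)(truth, syn)
            terms = _stage("synth")(generate_pathways)(truth)
            ts_table = _stage("synth")(generate_targetscan_table)(
                truth, mirna_seqs, utr_seqs
            )
            io.write_counts(mir_cm, inputs / "mirna_counts.tsv")
            io.write_counts(gene_cm, inputs / "mrna_counts.tsv")
            io.write_sample_sheet(mir_cm.groups, inputs / "samples.tsv")
            io.write_fasta(mirna_seqs, inputs / "mirna.fa", "RNA")
            io.write_fasta(utr_seqs, inputs / "utr.fa", "RNA")
            write_gmt(terms, inputs / "pathways.gmt")
            ts_table.to_csv(inputs / "targetscan.tsv", sep="\t", index=False)
            io.write_truth(truth, inputs / "truth.json")
            gmt_path = inputs / "pathways.gmt"
            ts_path = inputs / "targetscan.tsv"
        else:
            for attr in ("mirna_counts", "mrna_counts", "sample_sheet"):
                path = getattr(config, attr)
                if not path or not Path(path).exists():
                    raise StageError("inputs", f"missing input: {attr}={path}")
            mir_cm = io.read_counts(config.mirna_counts, config.sample_sheet, "miRNA")
            gene_cm = io.read_counts(config.mrna_counts, config.sample_sheet, "gene")
            mirna_seqs = io.read_fasta(config.mirna_fasta) if config.mirna_fasta else {}
            utr_seqs = io.read_fasta(config.utr_fasta) if config.utr_fasta else {}
            gmt_path = Path(config.gmt) if config.gmt else None
            ts_path = Path(config.targetscan_table) if config.targetscan_table else None

        # ---------------- QC -----------------------------------------
        @_stage("qc")
        def run_qc(cm):
            nz = qc.drop_zero_features(cm)
            filt = qc.prevalence_filter(nz, config.min_cpm, config.min_frac)
            return filt, qc.cpm(filt)

        mir_filt, mir_cpm = run_qc(mir_cm)
        gene_filt, gene_cpm = run_qc(gene_cm)
        io.write_counts(mir_filt, outdir / "mirna_counts_filtered.tsv")
        mir_cpm.cpm.to_csv(outdir / "mirna_cpm.tsv", sep="\t", index_label="feature")
        gene_cpm.cpm.to_csv(outdir / "mrna_cpm.tsv", sep="\t", index_label="feature")
        record("qc", "mirna_filtered", mir_filt.counts, outdir / "mirna_counts_filtered.tsv")
        record("qc", "mirna_cpm", mir_cpm.cpm, outdir / "mirna_cpm.tsv")
        record("qc", "mrna_cpm", gene_cpm.cpm, outdir / "mrna_cpm.tsv")

        # ---------------- DE ------------------------------------------
        @_stage("de")
        def run_de():
            factors = size_factors(mir_filt)
            recs = classify_demis(
                nb_wald_test(mir_filt, factors), config.p_thresh, config.fc_thresh
            )
            return recs

        de_records = run_de()
        de_df = de_table(de_records)
        io.write_table(de_df, outdir / "de_mirnas.tsv")
        record("de", "de_mirnas", de_df, outdir / "de_mirnas.tsv")
        io.write_table(volcano_table(de_records), outdir / "volcano.tsv")
        record("de", "volcano", de_df, outdir / "volcano.tsv")
        demis = [r.feature_id for r in de_records if r.status != "not_significant"]
        logger.info("DE: %d DEMIs of %d miRNAs", len(demis), len(de_records))

        # ---------------- target prediction ---------------------------
        @_stage("targets")
        def run_targets():
            if ts_path is None:
                raise ValueError("no TargetScan table supplied")
            preds = load_targetscan(ts_path, config.context_thresh)
            preds = [p for p in preds if p.mirna_id in set(demis)]
            return intersect_expressed(preds, set(gene_filt.feature_ids))

        predictions = run_targets()
        pred_df = pd.DataFrame(
            [(p.mirna_id, p.gene_id, p.cumulative_context_score) for p in predictions],
            columns=["miRNA", "gene", "context_score"],
        )
        io.write_table(pred_df, outdir / "predicted_targets.tsv")
        record("targets", "predicted_targets", pred_df, outdir / "predicted_targets.tsv")

        # ---------------- per-group PCIT networks ---------------------
        target_genes = sorted({p.gene_id for p in predictions})
        combined = pd.concat(
            [
                mir_cpm.cpm.loc[[d for d in demis if d in mir_cpm.cpm.index]],
                gene_cpm.cpm.loc[target_genes],
            ]
        )
        networks = {}
        for group in GROUPS:
            shared = [
                s
                for s in mir_cpm.cpm.columns
                if s in gene_cpm.cpm.columns and mir_cm.groups[s] == group
            ]
            norm = NormalizedMatrix(combined[shared], mir_cm.groups, "mixed")
            networks[group] = _stage(f"network-{group}")(build_group_network)(
                norm,
                demis,
                target_genes,
                group,
                config.r_min,
                samples=shared,
                scale=config.cpm_scale,
            )
            df = edges_table(networks[group])
            io.write_table(df, outdir / f"network_{group.lower()}.tsv")
            _write_sif(networks[group], outdir / f"network_{group.lower()}.sif")
            record(f"network-{group}", "edges", df, outdir / f"network_{group.lower()}.tsv")

        # ---------------- connectivity & rewiring ---------------------
        @_stage("connectivity")
        def run_conn():
            records = conn.differential_connectivity(
                networks["FH"], networks["SFH"], config.z_crit
            )
            rew = conn.dyn_rewiring(networks["FH"], networks["SFH"])
            central = conn.central_reference(networks["FH"], networks["SFH"])
            return records, rew, central

        conn_records, rew_records, central = run_conn()
        conn_df = conn.connectivity_table(conn_records)
        rew_df = conn.rewiring_table(rew_records)
        io.write_table(conn_df, outdir / "connectivity.tsv")
        io.write_table(rew_df, outdir / "rewiring.tsv")
        io.write_table(central, outdir / "central_reference.tsv")
        record("connectivity", "connectivity", conn_df, outdir / "connectivity.tsv")
        record("connectivity", "rewiring", rew_df, outdir / "rewiring.tsv")
        record("connectivity", "central_reference", central, outdir / "central_reference.tsv")

        # ---------------- duplex mfe ----------------------------------
        @_stage("mfe")
        def run_mfe():
            if not mirna_seqs or not utr_seqs:
                logger.warning("no sequences supplied; mfe stage skipped")
                return []
            in_network = set()
            for edges in networks.values():
                for e in edges:
                    in_network.add((e.node_a, e.node_b))
                    in_network.add((e.node_b, e.node_a))
            tx_by_gene: dict[str, list] = {}
            for tx in utr_seqs:
                tx_by_gene.setdefault(_tx_to_gene(tx), []).append(tx)
            records = []
            for p in predictions:
                if p.mirna_id not in mirna_seqs:
                    continue
                if not config.mfe_all_pairs and (p.mirna_id, p.gene_id) not in in_network:
                    continue
                for tx in sorted(tx_by_gene.get(p.gene_id, [])):
                    e, start = duplex_mfe(mirna_seqs[p.mirna_id], utr_seqs[tx])
                    records.append(
                        DuplexRecord(p.mirna_id, tx, p.gene_id, e, start)
                    )
            return gene_average_mfe(records, config.mfe_cutoff)

        mfe_records = run_mfe()
        mfe_df = duplex_table(mfe_records)
        io.write_table(mfe_df, outdir / "duplex_mfe.tsv")
        record("mfe", "duplex_mfe", mfe_df, outdir / "duplex_mfe.tsv")

        # ---------------- enrichment ----------------------------------
        @_stage("enrichment")
        def run_enrich():
            if gmt_path is None or not Path(gmt_path).exists():
                raise ValueError(f"no pathway GMT supplied ({gmt_path})")
            terms = read_gmt(gmt_path)
            universe = set().union(*terms.values()) | set(gene_filt.feature_ids)
            predicted_pairs = {(p.mirna_id, p.gene_id) for p in predictions}
            out = {}
            for group in GROUPS:
                # query = genes correlated with their own predicted miRNA
                # (the cognate TargetScan pairs present in this group's net)
                query = set()
                for e in networks[group]:
                    if e.edge_class != "miRNA-gene":
                        continue
                    m, g = (
                        (e.node_a, e.node_b)
                        if e.node_a in set(demis)
                        else (e.node_b, e.node_a)
                    )
                    if (m, g) in predicted_pairs:
                        query.add(g)
                if not query:
                    logger.warning("empty query set for group %s", group)
                    out[group] = []
                    continue
                out[group] = ora(query, terms, universe, kappa_min=config.kappa_min)
            return out

        enrich_out = run_enrich()
        for group, recs in enrich_out.items():
            df = enrichment_table(recs)
            io.write_table(df, outdir / f"enrichment_{group.lower()}.tsv")
            record("enrichment", group, df, outdir / f"enrichment_{group.lower()}.tsv")

        # ---------------- integrated pair table -----------------------
        pairs = _stage("summary")(summarize_pairs)(
            de_records, predictions, networks, mfe_records
        )
        io.write_table(pairs, outdir / "pairs_summary.tsv")
        record("summary", "pairs_summary", pairs, outdir / "pairs_summary.tsv")

        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
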