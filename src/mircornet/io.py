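"""Plain-text readers/writers for the pipeline's external formats.

Counts are TSV with features in rows (first column = feature id, header =
sample ids); the sample sheet is a two-column TSV (sample, group); FASTA
I/O goes through Biopython; the synthetic truth is serialized as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mircornet.containers import CountMatrix
from mircornet.synthetic import SyntheticTruth

FLOAT_FMT = "%.10g"


def write_counts(m: CountMatrix, path: str | Path) -> None:
    m.counts.to_csv(path, sep="\t", index_label="feature")


def write_sample_sheet(groups: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"sample": groups.index, "group": groups.values})
    df.sort_values("sample").to_csv(path, sep="\t", index=False)


def read_counts(
    counts_path: str | Path, sheet_path: str | Path, feature_kind: str = "gene"
) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sheet_path, sep="\t")
    groups = pd.Series(sheet["group"].values, index=sheet["sample"].values)
    return CountMatrix(counts, groups, feature_kind)


def write_fasta(seqs: dict[str, str], path: str | Path, alphabet: str = "RNA") -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description=f"alphabet={alphabet}")
        for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = asdict(truth)
    payload["target_pairs"] = [
        [m, g, list(groups)] for m, g, groups in truth.target_pairs
    ]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    payload["target_pairs"] = [
        (m, g, tuple(groups)) for m, g, groups in payload["target_pairs"]
    ]
    payload["de_mirnas"] = [tuple(x) for x in payload["de_mirnas"]]
    payload["planted_sites"] = [tuple(x) for x in payload["planted_sites"]]
    return SyntheticTruth(**payload)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
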