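"""File formats, configuration and model persistence.

Stable interchange formats: FASTA for sequences (multi-record; segments of one
virus are grouped through the metadata table), a tab-separated metadata table
with header ``id, order, family, genus, host_layer1, host_layer2`` (empty
field = absent; multiple layer-1 hosts separated by ``;`` mark a multi-label
record), a prediction TSV, and a model-bundle directory holding a joblib
pickle next to a JSON manifest with the format and feature-layout versions.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import VirusRecord
from .traits import FEATURE_LAYOUT_VERSION

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "write_predictions",
    "read_predictions",
    "match_ids",
    "save_bundle",
    "load_bundle",
]

BUNDLE_FORMAT_VERSION = "1"
METADATA_COLUMNS = ["id", "order", "family", "genus", "host_layer1", "host_layer2"]


@dataclasses.dataclass
class RunConfig:
    """Run-level configuration; every source of randomness flows from ``seed``."""

    seed: int
    feature_set: str = "sbias"
    learner: str = "xgboost"
    aligner_backend: str = "auto"
    gene_caller: str = "naive_orf"
    rejection_target: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_metadata(path: str | Path) -> list[VirusRecord]:
    """Read the metadata table; raises on malformed rows with the line number."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path}: missing columns {missing}")
    records = []
    seen = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        rid = row["id"].strip()
        if not rid:
            raise ValueError(f"metadata {path} line {line}: empty id")
        if rid in seen:
            raise ValueError(f"metadata {path} line {line}: duplicate id {rid!r}")
        seen.add(rid)
        hosts = tuple(h.strip() for h in row["host_layer1"].split(";") if h.strip())
        if not hosts:
            raise ValueError(f"metadata {path} line {line}: missing host_layer1")
        layer2 = row["host_layer2"].strip() or None
        if layer2 is not None and hosts[0] != "Chordata":
            raise ValueError(
                f"metadata {path} line {line}: host_layer2 set but host_layer1 is "
                f"{hosts[0]!r}, not Chordata"
            )
        records.append(
            VirusRecord(
                id=rid,
                order=row["order"].strip(),
                family=row["family"].strip() or None,
                genus=row["genus"].strip() or None,
                layer1_host=hosts[0],
                layer2_host=layer2,
                all_layer1_hosts=hosts,
            )
        )
    return records


def write_metadata(records: Iterable[VirusRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "order": r.order,
                "family": r.family or "",
                "genus": r.genus or "",
                "host_layer1": ";".join(r.all_layer1_hosts) or r.layer1_host,
                "host_layer2": r.layer2_host or "",
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def write_predictions(predictions: pd.DataFrame, path: str | Path) -> None:
    predictions.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["rejected"] = df["rejected"].astype(bool)
    if "note" in df.columns:
        df["note"] = df["note"].fillna("")
    return df


def match_ids(
    sequences: Mapping[str, str], records: Sequence[VirusRecord]
) -> dict[str, list[str]]:
    """Cross-validate FASTA and metadata ids; warns about and reports orphans."""
    seq_ids = set(sequences)
    rec_ids = {r.id for r in records}
    report = {
        "sequences_without_metadata": sorted(seq_ids - rec_ids),
        "metadata_without_sequence": sorted(rec_ids - seq_ids),
    }
    for key, orphans in report.items():
        if orphans:
            warnings.warn(f"{len(orphans)} {key.replace('_', ' ')}: {orphans[:5]}")
    return report


# ---------------------------------------------------------------------------
# model bundles


def save_bundle(predictor, directory: str | Path) -> None:
    """Persist a fitted predictor with a version-stamped manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(predictor, directory / "model.joblib")
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "feature_layout_version": getattr(
            predictor, "feature_layout_version_", FEATURE_LAYOUT_VERSION
        ),
        "aligner_backend": getattr(predictor, "aligner_backend_", None),
        "fingerprint": getattr(predictor, "fingerprint_", None),
        "params": predictor.get_params(),
    }
    (directory / "bundle.json").write_text(json.dumps(manifest, indent=2, default=str))


def load_bundle(directory: str | Path):
    """Load a bundle; version or layout mismatches raise instead of mispredicting."""
    directory = Path(directory)
    manifest_path = directory / "bundle.json"
    model_path = directory / "model.joblib"
    if not manifest_path.exists() or not model_path.exists():
        raise FileNotFoundError(f"{directory} is not a model bundle")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"bundle format {manifest.get('format_version')!r} incompatible with "
            f"supported version {BUNDLE_FORMAT_VERSION!r}"
        )
    if manifest.get("feature_layout_version") != FEATURE_LAYOUT_VERSION:
        raise ValueError(
            f"bundle feature layout {manifest.get('feature_layout_version')!r} "
            f"incompatible with {FEATURE_LAYOUT_VERSION!r}"
        )
    try:
        predictor = joblib.load(model_path)
    except Exception as exc:
        raise ValueError(f"corrupted model bundle at {directory}: {exc}") from exc
    return predictor
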