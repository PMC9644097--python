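"""Readers and writers for the pipeline's plain-text formats.

Canonical tabular dialect: tab-delimited, header row, UTF-8, '.' decimal.
Counts are features x samples with feature_id and biotype as the first two
columns; the sample sheet carries per-sample library sizes.  GFF3 (1-based
closed) is converted to the internal 0-based half-open convention on read;
BED6 is native.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import gffutils
import pandas as pd

from .assign import Feature, FeatureCatalog
from .matrix import CountMatrix
from .simulate import HC_TIMEPOINT, TIMEPOINTS

VALID_GROUPS = {"HC", "R", "NR"}
VALID_TIMEPOINTS = set(TIMEPOINTS) | {HC_TIMEPOINT}
_SHEET_REQUIRED = ["sample_id", "subject_id", "group", "timepoint"]


class SampleSheetError(ValueError):
    pass


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate a sample sheet TSV.

    Enforces required columns, controlled group/timepoint vocabularies, and
    unique sample ids; errors name the offending rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SHEET_REQUIRED if c not in df.columns]
    if missing:
        raise SampleSheetError(f"missing columns: {missing}")
    bad_group = df[~df["group"].isin(VALID_GROUPS)]
    if not bad_group.empty:
        raise SampleSheetError(
            f"unknown group labels in rows {bad_group.index.tolist()}: "
            f"{sorted(bad_group['group'].unique())}")
    bad_tp = df[~df["timepoint"].isin(VALID_TIMEPOINTS)]
    if not bad_tp.empty:
        raise SampleSheetError(
            f"unknown timepoints in rows {bad_tp.index.tolist()}: "
            f"{sorted(bad_tp['timepoint'].unique())}")
    dup = df[df["sample_id"].duplicated()]
    if not dup.empty:
        raise SampleSheetError(
            f"duplicate sample_id in rows {dup.index.tolist()}")
    if "library_size" in df.columns:
        df["library_size"] = df["library_size"].astype(int)
    return df


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def write_counts(cm: CountMatrix, path) -> None:
    """Counts TSV: feature_id, biotype, then one column per sample."""
    out = cm.counts.copy().sort_index()
    out.insert(0, "biotype", cm.biotype.loc[out.index])
    out.to_csv(path, sep="\t", index=True, index_label="feature_id")


def read_counts(path, library_size: pd.Series | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    biotype = df.pop("biotype")
    return CountMatrix(df, biotype, library_size)


def write_particles(particles: pd.DataFrame, path) -> None:
    particles.to_csv(path, sep="\t", index=False)


def read_particles(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if (df["concentration"] <= 0).any():
        raise ValueError("particle concentrations must be positive")
    return df


def write_bed(bed: pd.DataFrame, path) -> None:
    bed[["chrom", "start", "end", "read_id", "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "read_id", "score", "strand"])


def write_gff3(features: pd.DataFrame, path) -> None:
    """Write a feature annotation as GFF3 (converting to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in features.itertuples(index=False):
            attrs = f"ID={r.feature_id};biotype={r.biotype}"
            fh.write(
                f"{r.chrom}\tevcargo\t{r.biotype}\t{int(r.start) + 1}\t"
                f"{int(r.end)}\t.\t{r.strand}\t.\t{attrs}\n")


def read_gff3_catalog(path) -> FeatureCatalog:
    """Build a :class:`FeatureCatalog` from GFF3.

    The biotype comes from the ``biotype`` (or ``gene_biotype``) attribute;
    coordinates convert from GFF3 1-based closed to 0-based half-open.
    """
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    feats = []
    for f in db.all_features():
        attrs = dict(f.attributes)
        biotype = (attrs.get("biotype") or attrs.get("gene_biotype")
                   or [f.featuretype])[0]
        fid = (attrs.get("ID") or [f.id])[0]
        feats.append(Feature(fid, biotype, f.seqid, f.start - 1, f.end,
                             f.strand if f.strand in "+-" else ".",
                             source_db=f.source))
    return FeatureCatalog(feats)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outputs: dict, seed: int, config: dict, path) -> None:
    """Run manifest: seed, config hash, and a checksum per output file."""
    config_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "outputs": {name: {"path": str(p), "sha256": sha256_of(p)}
                    for name, p in outputs.items()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def validate_manifest(path) -> bool:
    """Re-hash every file listed in a manifest; True if all match."""
    with open(path) as fh:
        manifest = json.load(fh)
    return all(sha256_of(entry["path"]) == entry["sha256"]
               for entry in manifest["outputs"].values())
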