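"""Tab-delimited readers/writers for every pipeline table, plus config and
run-manifest helpers.

File dialects
-------------
* Matrices (expression, CN, methylation abundances): TSV, first column the
  row id, header row the sample ids, missing values written as ``NA``.
* Regions and chromosome arms: BED-like TSV (chromosome, start, end, name,
  optional direction), 0-based half-open coordinates.
* Config: YAML mapping of stage parameters.

Readers validate hard: duplicated ids and ragged rows are errors that name
the offending id or line, not silent coercions.
"""

from __future__ import annotations

import json
import logging
import sys
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .containers import (
    GenomicRegion,
    MethylationTable,
    MutationTable,
    OmicsCohort,
    ExpressionSignature,
)

log = logging.getLogger("ladomics")

NA_VALUES = ["", "NA"]


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("ladomics")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


# ---------------------------------------------------------------------------
# matrices

def _check_rectangular(path: Path) -> None:
    """Reject ragged TSV files, naming the first bad line (1-based)."""
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            ncol = line.rstrip("\n").count("\t") + 1
            if width is None:
                width = ncol
            elif ncol != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({ncol} fields, expected {width})"
                )


def _check_unique(ids, what: str, path: Path) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"{path}: duplicated {what} id {dups.index[0]!r}")


def read_matrix(path, index_name: str = "id") -> pd.DataFrame:
    """Read a TSV matrix (first column ids, header sample ids)."""
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=NA_VALUES, keep_default_na=False
    )
    _check_unique(df.index, "row", path)
    _check_unique(df.columns, "column", path)
    df.index.name = index_name
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples log-expression matrix.

    Raises if any row or column is entirely missing.
    """
    df = read_matrix(path, index_name="gene_id").astype(float)
    if df.isna().all(axis=1).any():
        gene = df.index[df.isna().all(axis=1)][0]
        raise ValueError(f"{path}: gene {gene!r} entirely missing")
    if df.isna().all(axis=0).any():
        sample = df.columns[df.isna().all(axis=0)][0]
        raise ValueError(f"{path}: sample {sample!r} entirely missing")
    return df


write_expression = write_matrix


# ---------------------------------------------------------------------------
# regions and arms

def read_regions(path) -> list[GenomicRegion]:
    """Read a BED-like region file (chrom, start, end, name[, direction])."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need >= 4 fields")
            chrom, start, end, name = fields[:4]
            direction = int(fields[4]) if len(fields) > 4 else 0
            try:
                regions.append(
                    GenomicRegion(chrom, int(start), int(end), name, direction)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_regions(regions: list[GenomicRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.name}\t{r.direction}\n")


def read_arms(path) -> pd.DataFrame:
    """Read chromosome arm definitions: arm_id, chromosome, start, end."""
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t")
    required = {"arm_id", "chromosome", "start", "end"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: arm table missing columns {sorted(missing)}")
    _check_unique(df["arm_id"], "arm", path)
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "arm_id"].iloc[0]
        raise ValueError(f"{path}: arm {bad!r} has start >= end")
    return df


def write_arms(arms: pd.DataFrame, path) -> None:
    arms.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CN, mutations, methylation, clinical

def read_cn(path) -> pd.DataFrame:
    """Read a probe CN table: probe_id, chromosome, position, <samples>."""
    df = read_matrix(path, index_name="probe_id")
    if "chromosome" not in df.columns or "position" not in df.columns:
        raise ValueError(f"{path}: CN table needs chromosome and position columns")
    df["position"] = df["position"].astype(int)
    if (df["position"] < 0).any():
        raise ValueError(f"{path}: negative probe position")
    sample_cols = [c for c in df.columns if c not in ("chromosome", "position")]
    df[sample_cols] = df[sample_cols].astype(float)
    return df


write_cn = write_matrix


def read_mutations(calls_path, assayed_path) -> MutationTable:
    calls_path = Path(calls_path)
    _check_rectangular(calls_path)
    calls = pd.read_csv(calls_path, sep="\t", dtype=str)
    assayed = read_matrix(assayed_path, index_name="gene")
    assayed = assayed.astype(float) > 0.5
    return MutationTable(calls=calls, assayed=assayed)


def write_mutations(mut: MutationTable, calls_path, assayed_path) -> None:
    mut.calls.to_csv(calls_path, sep="\t", index=False)
    mut.assayed.astype(int).to_csv(assayed_path, sep="\t", na_rep="NA")


def read_methylation(sites_path, undigested_path, hpaii_path) -> MethylationTable:
    sites = read_matrix(sites_path, index_name="site_id")
    sites["position"] = sites["position"].astype(int)
    und = read_matrix(undigested_path, index_name="site_id").astype(float)
    hpa = read_matrix(hpaii_path, index_name="site_id").astype(float)
    return MethylationTable(sites=sites, undigested=und, hpaii=hpa)


def write_methylation(meth: MethylationTable, sites_path, undigested_path, hpaii_path) -> None:
    write_matrix(meth.sites, sites_path)
    write_matrix(meth.undigested, undigested_path)
    write_matrix(meth.hpaii, hpaii_path)


def read_clinical(path) -> pd.DataFrame:
    df = read_matrix(path, index_name="sample_id")
    df["followup_months"] = df["followup_months"].astype(float)
    df["event"] = df["event"].astype(float).astype(bool)
    if (df["followup_months"] < 0).any():
        raise ValueError(f"{path}: negative follow-up time")
    return df


write_clinical = write_matrix


def read_signature(path) -> ExpressionSignature:
    """Two-column gene list: gene, list ('over' or 'under')."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    over = tuple(df.loc[df["list"] == "over", "gene"])
    under = tuple(df.loc[df["list"] == "under", "gene"])
    return ExpressionSignature(over, under)


def write_signature(sig: ExpressionSignature, path) -> None:
    rows = [(g, "over") for g in sig.overexpressed] + [
        (g, "under") for g in sig.underexpressed
    ]
    pd.DataFrame(rows, columns=["gene", "list"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# whole cohorts

_COHORT_FILES = {
    "expression": "expression.tsv",
    "cn": "cn_probes.tsv",
    "calls": "mutation_calls.tsv",
    "assayed": "mutation_assayed.tsv",
    "meth_sites": "methylation_sites.tsv",
    "meth_und": "methylation_undigested.tsv",
    "meth_hpa": "methylation_hpaii.tsv",
    "clinical": "clinical.tsv",
    "roles": "sample_roles.tsv",
    "bases": "sequenced_bases.tsv",
    "arms": "arms.tsv",
    "regions": "regions.bed",
    "gene_positions": "gene_positions.tsv",
    "signature": "signature.tsv",
}


def write_cohort(cohort: OmicsCohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    f = {k: out / v for k, v in _COHORT_FILES.items()}
    if cohort.expression is not None:
        write_expression(cohort.expression, f["expression"])
    if cohort.cn is not None:
        write_cn(cohort.cn, f["cn"])
    if cohort.mutations is not None:
        write_mutations(cohort.mutations, f["calls"], f["assayed"])
    if cohort.methylation is not None:
        write_methylation(
            cohort.methylation, f["meth_sites"], f["meth_und"], f["meth_hpa"]
        )
    if cohort.clinical is not None:
        write_clinical(cohort.clinical, f["clinical"])
    if cohort.sample_roles is not None:
        cohort.sample_roles.rename("role").to_frame().to_csv(f["roles"], sep="\t")
    if cohort.sequenced_bases is not None:
        cohort.sequenced_bases.rename("bases").to_frame().to_csv(f["bases"], sep="\t")
    if cohort.arms is not None:
        write_arms(cohort.arms, f["arms"])
    if cohort.regions:
        write_regions(cohort.regions, f["regions"])
    if cohort.gene_positions is not None:
        write_matrix(cohort.gene_positions, f["gene_positions"])
    if cohort.signature is not None:
        write_signature(cohort.signature, f["signature"])


def read_cohort(in_dir) -> OmicsCohort:
    d = Path(in_dir)
    f = {k: d / v for k, v in _COHORT_FILES.items()}
    cohort = OmicsCohort()
    if f["expression"].exists():
        cohort.expression = read_expression(f["expression"])
    if f["cn"].exists():
        cohort.cn = read_cn(f["cn"])
    if f["calls"].exists():
        cohort.mutations = read_mutations(f["calls"], f["assayed"])
    if f["meth_sites"].exists():
        cohort.methylation = read_methylation(
            f["meth_sites"], f["meth_und"], f["meth_hpa"]
        )
    if f["clinical"].exists():
        cohort.clinical = read_clinical(f["clinical"])
    if f["roles"].exists():
        roles = pd.read_csv(f["roles"], sep="\t", index_col=0)
        cohort.sample_roles = roles["role"]
    if f["bases"].exists():
        bases = pd.read_csv(f["bases"], sep="\t", index_col=0)
        cohort.sequenced_bases = bases["bases"].astype(float)
    if f["arms"].exists():
        cohort.arms = read_arms(f["arms"])
    if f["regions"].exists():
        cohort.regions = read_regions(f["regions"])
    if f["gene_positions"].exists():
        gp = read_matrix(f["gene_positions"], index_name="gene")
        gp["position"] = gp["position"].astype(int)
        cohort.gene_positions = gp
    if f["signature"].exists():
        cohort.signature = read_signature(f["signature"])
    return cohort


# ---------------------------------------------------------------------------
# config and manifest

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_manifest(out_dir, *, command: str, seed: int | None,
                   parameters: dict, inputs: list[str], outputs: list[str]) -> Path:
    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "parameters": parameters,
        "inputs": inputs,
        "outputs": sorted(outputs),
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
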