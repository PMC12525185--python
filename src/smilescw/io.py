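"""Dataset readers/writers, model serialization and report writers.

Datasets are delimited text (CSV/TSV with columns id, smiles, endpoint, or
.smi-style whitespace-delimited "SMILES id [endpoint]").  Models are JSON
artifacts that round-trip bit-exactly; every tabular artifact embeds the
seed, a config hash and the software version in comment header lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._version import __version__
from .applicability import DefectRecord, DomainModel
from .errors import DatasetError, MalformedSmilesError, ModelIOError
from .optimizer import OptimizationConfig, OptimizationHistory
from .tokenizer import SmilesRecord, normalize_smiles, tokenize
from .weights import CorrelationWeightTable, FittedModel

__all__ = [
    "read_dataset",
    "write_dataset",
    "save_model",
    "load_model",
    "config_hash",
    "write_history",
    "write_stats_table",
    "write_promoter_table",
    "write_domain_report",
    "aggregate_scores",
    "summarize_runs",
]

MODEL_FORMAT = "smilescw-model"
MODEL_FORMAT_VERSION = 1


def config_hash(config: OptimizationConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _artifact_header(seed, cfg_hash) -> str:
    return (
        f"# smilescw {__version__}\n"
        f"# seed={seed}\n"
        f"# config_hash={cfg_hash}\n"
    )


def read_dataset(path, fmt: Optional[str] = None, strict: bool = True) -> list:
    """Parse a dataset file into SmilesRecords.

    ``fmt`` is one of "csv", "tsv", "smi" (inferred from the suffix when
    omitted).  Rows whose SMILES does not tokenize are fatal when ``strict``
    (the default) and skipped with their line numbers reported otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = suffix if suffix in ("csv", "tsv", "smi") else "csv"
    if fmt in ("csv", "tsv"):
        frame = pd.read_csv(path, sep="," if fmt == "csv" else "\t", comment="#")
        frame.columns = [str(c).strip().lower() for c in frame.columns]
        missing = {"id", "smiles"} - set(frame.columns)
        if missing:
            raise DatasetError(f"{path}: missing column(s) {sorted(missing)}")
        rows = [
            (
                i + 2,  # header is line 1
                str(row["id"]),
                str(row["smiles"]),
                None if "endpoint" not in frame.columns or pd.isna(row["endpoint"])
                else float(row["endpoint"]),
            )
            for i, row in frame.iterrows()
        ]
    else:  # .smi-style: SMILES id [endpoint]
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise DatasetError(f"{path}:{lineno}: expected 'SMILES id [endpoint]'")
                endpoint = float(parts[2]) if len(parts) > 2 else None
                rows.append((lineno, parts[1], parts[0], endpoint))
    if not rows:
        raise DatasetError(f"{path}: dataset is empty")
    records = []
    seen = set()
    bad_lines = []
    for lineno, cid, smiles, endpoint in rows:
        if cid in seen:
            raise DatasetError(f"{path}: duplicate id {cid!r}")
        seen.add(cid)
        try:
            tokenize(normalize_smiles(smiles))
        except MalformedSmilesError as exc:
            if strict:
                raise DatasetError(f"{path}:{lineno}: bad SMILES for {cid!r}: {exc}")
            bad_lines.append(lineno)
            continue
        records.append(SmilesRecord(id=cid, smiles=smiles, endpoint=endpoint))
    if bad_lines:
        import warnings

        warnings.warn(f"{path}: skipped unparseable SMILES on lines {bad_lines}")
    if not records:
        raise DatasetError(f"{path}: no parseable records")
    return records


def write_dataset(records: Sequence[SmilesRecord], path) -> None:
    frame = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "endpoint": [r.endpoint for r in records],
        }
    )
    frame.to_csv(path, index=False)


def save_model(model: FittedModel, path) -> None:
    """Serialize a fitted model to JSON (bit-exact float round-trip)."""
    domain = model.domain
    payload = {
        "format": MODEL_FORMAT,
        "format_version": MODEL_FORMAT_VERSION,
        "software_version": __version__,
        "metadata": dict(model.metadata),
        "config": dataclasses.asdict(model.config),
        "config_hash": config_hash(model.config),
        "c0": model.c0,
        "c1": model.c1,
        "table": {
            "threshold_T": model.table.threshold_T,
            "weights": dict(model.table.weights),
            "blocked": sorted(model.table.blocked),
        },
        "domain": None
        if domain is None
        else {
            "dbar": domain.dbar,
            "mean_set": domain.mean_set,
            "set_sizes": dict(domain.set_sizes),
            "known": sorted(domain.known),
            "defects": {
                attr: {
                    "nA": rec.nA, "nP": rec.nP, "nC": rec.nC,
                    "pA": rec.pA, "pP": rec.pP, "pC": rec.pC, "dk": rec.dk,
                }
                for attr, rec in domain.defects.items()
            },
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path) -> FittedModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if payload.get("format") != MODEL_FORMAT:
        raise ModelIOError(f"{path}: not a {MODEL_FORMAT} artifact")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"{path}: unsupported format version {payload.get('format_version')}"
        )
    cfg = payload["config"]
    cfg["init_range"] = tuple(cfg["init_range"])
    config = OptimizationConfig(**cfg)
    table = CorrelationWeightTable(
        weights=payload["table"]["weights"],
        blocked=frozenset(payload["table"]["blocked"]),
        threshold_T=payload["table"]["threshold_T"],
    )
    domain = None
    raw = payload.get("domain")
    if raw is not None:
        defects = {
            attr: DefectRecord(attribute=attr, **rec)
            for attr, rec in raw["defects"].items()
        }
        domain = DomainModel(
            defects=defects,
            dbar=raw["dbar"],
            set_sizes=raw["set_sizes"],
            known=frozenset(raw["known"]),
            mean_set=raw["mean_set"],
        )
    return FittedModel(
        table=table,
        c0=payload["c0"],
        c1=payload["c1"],
        config=config,
        domain=domain,
        metadata=payload.get("metadata", {}),
    )


def write_history(history: OptimizationHistory, path, seed, cfg_hash) -> None:
    with open(path, "w") as fh:
        fh.write(_artifact_header(seed, cfg_hash))
        history.to_dataframe().to_csv(fh, index=False)


def _fmt(value, kind: str) -> str:
    if value is None:
        return "-"
    if kind == "r":  # R²-family, 4 decimals
        return f"{value:.4f}"
    if kind == "e":  # error magnitudes, 3 significant figures
        return f"{value:.3g}"
    if kind == "f":  # F-ratio, nearest integer
        return str(int(round(value)))
    return str(value)


def write_stats_table(
    bundles: dict, path, seed=None, cfg_hash=None, mirror_validation: bool = True
) -> None:
    """Write set-level statistics as a TSV shaped like the published tables.

    Rows are the sets A/P/C/V; columns n, R², CCC, IIC, Q², RMSE, MAE, F.
    With ``mirror_validation`` (default) the validation row reports only n,
    R², RMSE and MAE, as the published layout does.
    """
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(_artifact_header(seed, cfg_hash))
        fh.write("set\tn\tr2\tccc\tiic\tq2\trmse\tmae\tf\n")
        for label in ("A", "P", "C", "V"):
            bundle = bundles.get(label)
            if bundle is None:
                continue
            hide = mirror_validation and label == "V"
            fh.write(
                "\t".join(
                    [
                        label,
                        str(bundle.n),
                        _fmt(bundle.r2, "r"),
                        "-" if hide else _fmt(bundle.ccc, "r"),
                        "-" if hide else _fmt(bundle.iic, "r"),
                        "-" if hide else _fmt(bundle.q2, "r"),
                        _fmt(bundle.rmse, "e"),
                        _fmt(bundle.mae, "e"),
                        "-" if hide else _fmt(bundle.f, "f"),
                    ]
                )
                + "\n"
            )


def write_promoter_table(promoters, path, seed=None, cfg_hash=None) -> None:
    """Promoter TSV: attribute, per-probe weights, frequencies, defect."""
    n_probes = len(promoters[0].weights) if promoters else 0
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(_artifact_header(seed, cfg_hash))
        cols = ["attribute"] + [f"cw_probe_{i + 1}" for i in range(n_probes)]
        cols += ["classification", "nA", "nP", "nC", "dk"]
        fh.write("\t".join(cols) + "\n")
        for rec in promoters:
            row = [rec.attribute]
            row += [f"{w:.4f}" for w in rec.weights]
            row += [
                rec.classification,
                str(rec.nA), str(rec.nP), str(rec.nC),
                "-" if rec.dk is None else f"{rec.dk:.4f}",
            ]
            fh.write("\t".join(row) + "\n")


def write_domain_report(domain: DomainModel, compounds, path_attributes, path_compounds,
                        seed=None, cfg_hash=None) -> None:
    """Per-attribute defect table and per-compound domain table.

    ``compounds`` is an iterable of (id, set_label, Dj, in_domain) tuples.
    """
    with open(path_attributes, "w") as fh:
        if seed is not None:
            fh.write(_artifact_header(seed, cfg_hash))
        fh.write("attribute\tnA\tnP\tnC\tdk\n")
        for attr, rec in domain.defects.items():
            fh.write(f"{attr}\t{rec.nA}\t{rec.nP}\t{rec.nC}\t{rec.dk:.4f}\n")
    with open(path_compounds, "w") as fh:
        if seed is not None:
            fh.write(_artifact_header(seed, cfg_hash))
        fh.write("id\tset\tDj\tin_domain\n")
        for cid, label, dj, ok in compounds:
            fh.write(f"{cid}\t{label}\t{dj:.6f}\t{int(ok)}\n")


def aggregate_scores(values: Sequence[float]) -> dict:
    """Mean and dispersion (population and sample SD) of per-split scores."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no values to aggregate")
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "sd_pop": float(arr.std(ddof=0)),
        "sd_sample": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    }


def summarize_runs(run_rows: Sequence[dict]) -> pd.DataFrame:
    """Aggregate per-split set statistics into a target-function comparison.

    ``run_rows`` holds one dict per (run, set) with keys target, split_id,
    set, r2, rmse.  Returns mean ± dispersion of R² and RMSE per (target,
    set), the comparison summary used to contrast the two target functions.
    """
    frame = pd.DataFrame(list(run_rows))
    required = {"target", "split_id", "set", "r2", "rmse"}
    if not required.issubset(frame.columns):
        raise ValueError(f"run rows need columns {sorted(required)}")
    out_rows = []
    for (target, set_label), group in frame.groupby(["target", "set"], sort=True):
        r2_stats = aggregate_scores(group["r2"])
        rmse_stats = aggregate_scores(group["rmse"])
        out_rows.append(
            {
                "target": target,
                "set": set_label,
                "n_splits": r2_stats["n"],
                "r2_mean": r2_stats["mean"],
                "r2_sd_pop": r2_stats["sd_pop"],
                "r2_sd_sample": r2_stats["sd_sample"],
                "rmse_mean": rmse_stats["mean"],
                "rmse_sd_pop": rmse_stats["sd_pop"],
                "rmse_sd_sample": rmse_stats["sd_sample"],
            }
        )
    return pd.DataFrame(out_rows)
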