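"""Readers and writers for the package's table, tree and report formats.

CSV dialects follow R-flavoured conventions: missing cells are empty or
``NA``; coordinates are signed decimal degrees with latitude before
longitude; taxonomy paths are pipe-delimited classification labels.  Trees
are standard Newick with branch lengths.  Winnow reports render to one TSV
per stage table, a plain-text status trail and a machine-readable JSON twin
with deterministic ordering.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .model_compare import WinnowReport
from .taxonomy_tree import CladeSpec, Hierarchy, LanguageTaxonomy, TaxonEntry

__all__ = [
    "RunConfig",
    "read_trait_table",
    "write_trait_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_coordinates",
    "write_coordinates",
    "read_newick",
    "write_newick",
    "render_report",
    "load_run_config",
]

log = logging.getLogger("phylospatial")

_MISSING = {"", "NA"}


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Trait CSV: first column society_id, remaining columns numeric.

    Empty cells and ``NA`` are missing; any other non-numeric cell raises an
    error naming its row and column.  Duplicate society ids raise.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    id_col = raw.columns[0]
    ids = raw[id_col]
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate society_id(s): {dupes}")
    out = {}
    for col in raw.columns[1:]:
        vals = []
        for sid, cell in zip(ids, raw[col]):
            cell = cell.strip()
            if cell in _MISSING:
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {sid!r}, column {col!r}"
                ) from None
        out[col] = vals
    table = pd.DataFrame(out, index=pd.Index(ids, name="society_id"))
    log.info("read trait table %s: %d rows, %d columns", path, *table.shape)
    return table


def write_trait_table(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index_label="society_id", na_rep="NA")


def read_taxonomy(
    path_taxa: str | Path, path_clades: str | Path
) -> tuple[LanguageTaxonomy, list[CladeSpec]]:
    """Taxonomy CSV (tip_id, language_code, clade_id, path, sample_level) and
    clade CSV (clade_id, relative_height, max_level, n_languages)."""
    clade_df = pd.read_csv(path_clades)
    clades = [
        CladeSpec(
            clade_id=str(r.clade_id),
            relative_height=float(r.relative_height),
            max_level=int(r.max_level),
            n_languages=int(getattr(r, "n_languages", 0) or 0),
        )
        for r in clade_df.itertuples(index=False)
    ]
    known = {c.clade_id for c in clades}
    taxa_df = pd.read_csv(path_taxa)
    entries = []
    for r in taxa_df.itertuples(index=False):
        cid = str(r.clade_id)
        if cid not in known:
            raise ValueError(f"tip {r.tip_id!r} references unknown clade {cid!r}")
        entries.append(
            TaxonEntry(
                tip_id=str(r.tip_id),
                language_code=str(r.language_code),
                clade_id=cid,
                path=tuple(str(r.path).split("|")),
                sample_level=int(r.sample_level),
            )
        )
    taxonomy = LanguageTaxonomy(entries=entries)
    for c in clades:
        for e in taxonomy.entries:
            if e.clade_id == c.clade_id and e.sample_level > c.max_level:
                raise ValueError(
                    f"tip {e.tip_id!r}: sample_level {e.sample_level} exceeds "
                    f"max_level {c.max_level} of clade {c.clade_id!r}"
                )
    return taxonomy, clades


def write_taxonomy(
    taxonomy: LanguageTaxonomy,
    clades: Iterable[CladeSpec],
    path_taxa: str | Path,
    path_clades: str | Path,
) -> None:
    pd.DataFrame(
        [
            {
                "tip_id": e.tip_id,
                "language_code": e.language_code,
                "clade_id": e.clade_id,
                "path": "|".join(e.path),
                "sample_level": e.sample_level,
            }
            for e in taxonomy.entries
        ]
    ).to_csv(path_taxa, index=False)
    pd.DataFrame(
        [
            {
                "clade_id": c.clade_id,
                "relative_height": c.relative_height,
                "max_level": c.max_level,
                "n_languages": c.n_languages,
            }
            for c in clades
        ]
    ).to_csv(path_clades, index=False)


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Coordinates CSV: society_id, lat, lon in signed decimal degrees."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    df.index.name = "society_id"
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate society_id(s): {dupes}")
    return df[["lat", "lon"]].astype(float)


def write_coordinates(coords: pd.DataFrame, path: str | Path) -> None:
    coords.to_csv(path, index_label="society_id")


def write_newick(tree: Hierarchy, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def read_newick(path: str | Path) -> Hierarchy:
    return Hierarchy.from_newick(Path(path).read_text(encoding="utf-8"))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj

def _records(df: pd.DataFrame) -> list[dict]:
    if df is None or df.empty:
        return []
    clean = df.replace({np.nan: None})
    return [_jsonable(rec) for rec in clean.to_dict(orient="records")]


def render_report(report: WinnowReport, outdir: str | Path) -> list[Path]:
    """Write stage TSVs, the plain-text status trail and the JSON twin.

    Output is deterministic for a given report: fixed file set, fixed row
    ordering (as produced by the pipeline), ``NA`` for missing cells.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for name, stage in (
        ("stage1", report.stage1),
        ("stage2", report.stage2),
        ("stage3", report.stage3),
    ):
        p = outdir / f"{name}.tsv"
        table = stage.table if not stage.table.empty else pd.DataFrame(
            columns=["y", "x"]
        )
        table.to_csv(p, sep="\t", index=False, na_rep="NA", float_format="%.6g")
        written.append(p)
    if report.screen is not None:
        p = outdir / "kendall_tau.tsv"
        report.screen.tau.to_csv(p, sep="\t", na_rep="NA", float_format="%.6g")
        written.append(p)

    trail_path = outdir / "status_trail.txt"
    lines = [
        f"stage {r['stage']}: {r['variable']} {r['status']} -- {r['test']}"
        for r in report.trail
    ]
    trail_path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    written.append(trail_path)

    twin = {
        "stage1": _records(report.stage1.table),
        "stage2": _records(report.stage2.table),
        "stage3": _records(report.stage3.table),
        "trail": _jsonable(report.trail),
        "final_retained": list(report.final_retained),
        "verdicts": _jsonable(report.verdicts),
    }
    json_path = outdir / "report.json"
    json_path.write_text(
        json.dumps(twin, indent=2, sort_keys=True, allow_nan=False) + "\n",
        encoding="utf-8",
    )
    written.append(json_path)
    return written


@dataclasses.dataclass
class RunConfig:
    """File paths, variable roles and thresholds for a full pipeline run."""

    traits_path: str
    taxonomy_path: str
    clades_path: str
    coordinates_path: str
    cultural_vars: tuple[str, ...]
    parasite_vars: tuple[str, ...]
    covariate_sets: dict[str, tuple[str, ...]] = dataclasses.field(default_factory=dict)
    mode: str = "nugget"
    alpha: float = 0.05
    bonferroni_m: int = 16
    aic_threshold: float = 2.0
    seed: int = 0
    outdir: str = "winnow_out"


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    data["cultural_vars"] = tuple(data["cultural_vars"])
    data["parasite_vars"] = tuple(data["parasite_vars"])
    data["covariate_sets"] = {
        k: tuple(v) for k, v in (data.get("covariate_sets") or {}).items()
    }
    return RunConfig(**data)
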