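"""Reading, writing and validation of every on-disk artifact of the pipeline.

All artifacts are plain tab-separated UTF-8 text with a single header line and
a locale-independent decimal point:

* **plate list** — columns ``screen_id, condition, replicate, plate_id,
  filename``; maps each intensity file to its place in the replicate
  structure.
* **well annotation** — columns ``plate_id, well, content, gene_id``; the
  shared physical layout of every replicate plate.
* **intensity file** — columns ``well, intensity``; one plate-read of raw
  relative luminescence (or ATP luminescence for the orthogonal viability
  screen).
* result tables (scores, differential scores, hits) — written via
  :func:`write_table` / :func:`read_table` with 10 significant digits, which
  round-trips all values to well below 1e-9 relative error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .design import (
    CONTENT_CLASSES,
    LibraryDesign,
    parse_well,
)

#: Experimental conditions: replicate sets exposed to cytotoxic T lymphocytes
#: (``with_ctl``, the toxicity set), incubated without them (``without_ctl``,
#: the viability set), and the orthogonal ATP-based readout (``ctg``).
CONDITIONS = ("with_ctl", "without_ctl", "ctg")

#: Column order of the canonical well-record frame.
WELL_COLUMNS = (
    "screen_id",
    "condition",
    "replicate",
    "plate_id",
    "well",
    "content",
    "gene_id",
    "intensity",
)

_FLOAT_FMT = "%.10g"


class ScreenValidationError(ValueError):
    """A dataset violates a well-record or replicate-structure invariant."""


@dataclass
class ScreenDataset:
    """All measured wells of one multi-screen experiment.

    ``wells`` holds one row per measured well with the columns in
    :data:`WELL_COLUMNS`; ``library`` is the shared design; ``provenance``
    records where the data came from (file paths or generator seed/version).
    """

    wells: pd.DataFrame
    library: LibraryDesign
    provenance: Mapping[str, Any] = field(default_factory=dict)

    def validate(self, expected_replicates: int = 2) -> "ScreenDataset":
        """Check every invariant; return self or raise ScreenValidationError."""
        w = self.wells
        missing = set(WELL_COLUMNS) - set(w.columns)
        if missing:
            raise ScreenValidationError(f"well table missing columns {sorted(missing)}")

        bad_cond = set(w["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ScreenValidationError(f"unknown conditions {sorted(bad_cond)}")
        bad_content = set(w["content"]) - set(CONTENT_CLASSES)
        if bad_content:
            raise ScreenValidationError(f"unknown content classes {sorted(bad_content)}")

        if (w["replicate"] < 1).any():
            raise ScreenValidationError("replicate numbers must be positive")

        for well in w["well"]:
            parse_well(well)  # raises on malformed labels

        inten = w["intensity"].to_numpy(dtype=float)
        if not np.isfinite(inten).all() or (inten < 0).any():
            bad = w.loc[~np.isfinite(inten) | (inten < 0)]
            locs = ", ".join(f"{r.plate_id}:{r.well}" for r in bad.head(10).itertuples())
            raise ScreenValidationError(f"negative or non-finite intensities at {locs}")

        is_sample = w["content"] == "sample"
        has_gene = w["gene_id"].notna()
        if (is_sample != has_gene).any():
            raise ScreenValidationError(
                "gene_id must be present exactly for sample wells"
            )

        unknown = set(w.loc[is_sample, "gene_id"]) - set(self.library.genes)
        if unknown:
            raise ScreenValidationError(
                f"sample gene_ids absent from library: {sorted(unknown)[:10]}"
            )

        key = ["screen_id", "condition", "replicate", "plate_id", "well"]
        dup = w.duplicated(subset=key)
        if dup.any():
            d = w.loc[dup, key].head(5).to_dict("records")
            raise ScreenValidationError(f"duplicate wells: {d}")

        reps = (
            w.loc[w["condition"] != "ctg"]
            .groupby(["screen_id", "condition"])["replicate"]
            .nunique()
        )
        wrong = reps[reps != expected_replicates]
        if len(wrong):
            raise ScreenValidationError(
                f"expected {expected_replicates} replicates per (screen, condition), "
                f"got {wrong.to_dict()}"
            )
        return self


# ---------------------------------------------------------------------------
# generic result-table I/O

def write_table(table: pd.DataFrame, path: str | Path, *, index: bool = True) -> Path:
    """Write a result table as TSV with a stable column order.

    Floats are written with 10 significant digits so a read-back reproduces
    every value to <= 1e-9 relative error; an empty table yields a file with
    the header line only.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)
    return path


def read_table(path: str | Path, *, index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table file: {path}")
    return pd.read_csv(path, sep="\t", index_col=index_col)


# ---------------------------------------------------------------------------
# screen ingestion

def _read_tsv(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in required if c != "intensity"})
    missing = set(required) - set(df.columns)
    if missing:
        raise ScreenValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_screen(
    plate_list_path: str | Path,
    annotation_path: str | Path,
    library: LibraryDesign | None = None,
    *,
    expected_replicates: int = 2,
) -> ScreenDataset:
    """Assemble and validate a :class:`ScreenDataset` from disk.

    The plate list maps each intensity file (path relative to the plate list)
    to its (screen, condition, replicate, plate); the annotation maps each
    (plate, well) to its content class and gene. Every well present in an
    intensity file must be annotated.

    If no ``library`` is given, one is constructed from the annotated sample
    genes in annotation order.
    """
    plate_list_path = Path(plate_list_path)
    annotation_path = Path(annotation_path)
    plates = _read_tsv(
        plate_list_path,
        ("screen_id", "condition", "replicate", "plate_id", "filename"),
    )
    anno = _read_tsv(annotation_path, ("plate_id", "well", "content", "gene_id"))
    anno["gene_id"] = anno["gene_id"].replace({"": None, "NA": None})
    anno.loc[anno["content"] != "sample", "gene_id"] = None

    if library is None:
        genes = tuple(anno.loc[anno["content"] == "sample", "gene_id"].dropna().unique())
        library = LibraryDesign(genes=genes)

    anno_key = anno.set_index(["plate_id", "well"])
    frames = []
    for rec in plates.itertuples():
        fpath = plate_list_path.parent / rec.filename
        inten = _read_tsv(fpath, ("well", "intensity"))
        inten["intensity"] = pd.to_numeric(inten["intensity"], errors="raise")
        keys = list(zip([rec.plate_id] * len(inten), inten["well"]))
        unknown = [k for k in keys if k not in anno_key.index]
        if unknown:
            names = ", ".join(f"{p}:{w}" for p, w in unknown[:10])
            raise ScreenValidationError(
                f"{fpath}: wells missing from annotation: {names}"
            )
        joined = anno_key.loc[keys].reset_index()
        frames.append(
            pd.DataFrame(
                {
                    "screen_id": rec.screen_id,
                    "condition": rec.condition,
                    "replicate": int(rec.replicate),
                    "plate_id": rec.plate_id,
                    "well": inten["well"].to_numpy(),
                    "content": joined["content"].to_numpy(),
                    "gene_id": joined["gene_id"].to_numpy(),
                    "intensity": inten["intensity"].to_numpy(),
                }
            )
        )
    wells = pd.concat(frames, ignore_index=True)[list(WELL_COLUMNS)]
    ds = ScreenDataset(
        wells=wells,
        library=library,
        provenance={
            "plate_list": str(plate_list_path),
            "annotation": str(annotation_path),
        },
    )
    return ds.validate(expected_replicates=expected_replicates)


def intensity_filename(screen_id: str, condition: str, replicate: int, plate_id: str) -> str:
    return f"intensities/{screen_id}_{condition}_r{replicate}_{plate_id}.tsv"


def write_screen(dataset: ScreenDataset, outdir: str | Path) -> Path:
    """Write a dataset as a complete on-disk fixture readable by read_screen.

    Produces ``plate_list.tsv``, ``annotation.tsv`` and one intensity file per
    (screen, condition, replicate, plate).
    """
    outdir = Path(outdir)
    (outdir / "intensities").mkdir(parents=True, exist_ok=True)
    w = dataset.wells

    anno = (
        w[["plate_id", "well", "content", "gene_id"]]
        .drop_duplicates(subset=["plate_id", "well"])
        .sort_values(["plate_id", "well"], kind="mergesort")
    )
    write_table(anno, outdir / "annotation.tsv", index=False)

    rows = []
    for (screen, cond, rep, plate), grp in w.groupby(
        ["screen_id", "condition", "replicate", "plate_id"], sort=True
    ):
        fname = intensity_filename(screen, cond, rep, plate)
        write_table(grp[["well", "intensity"]], outdir / fname, index=False)
        rows.append((screen, cond, rep, plate, fname))
    plate_list = pd.DataFrame(
        rows, columns=["screen_id", "condition", "replicate", "plate_id", "filename"]
    )
    write_table(plate_list, outdir / "plate_list.tsv", index=False)
    return outdir


# ---------------------------------------------------------------------------
# score/differential table layout helpers

def flatten_score_columns(scores: pd.DataFrame) -> pd.DataFrame:
    """Flatten MultiIndex (screen, condition[, replicate]) columns to strings."""
    out = scores.copy()
    cols = []
    for col in scores.columns:
        if len(col) == 3:
            cols.append(f"{col[0]}_{col[1]}_r{col[2]}")
        else:
            cols.append(f"{col[0]}_{col[1]}")
    out.columns = cols
    return out


def unflatten_score_columns(flat: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`flatten_score_columns` using the known condition names."""
    tuples = []
    for col in flat.columns:
        for cond in CONDITIONS:
            tag = f"_{cond}"
            if col.endswith(tag):
                tuples.append((col[: -len(tag)], cond))
                break
            if tag + "_r" in col:
                screen, rep = col.split(tag + "_r")
                tuples.append((screen, cond, int(rep)))
                break
        else:
            raise ScreenValidationError(f"cannot parse score column {col!r}")
    out = flat.copy()
    out.columns = pd.MultiIndex.from_tuples(tuples)
    return out
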