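"""Reading and writing the study's plain-text exchange formats.

Matrices are TSVs with ``protein_id`` as the first column and one column per
sample; sample descriptors live in sidecar ``*_meta.tsv`` files mapping
``sample_id`` to cell line/pool, compartment and case/control group.
Annotation sets use GMT (term, description, tab-separated symbols).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import DataError
from .synthetic import SimulatedProteomics


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Protein x sample TSV, first column ``protein_id``."""
    df = pd.read_csv(path, sep="\t")
    if df.empty or df.shape[1] < 2:
        raise DataError(f"{path}: expected a protein_id column plus >= 1 sample column")
    first = df.columns[0]
    if first != "protein_id":
        raise DataError(f"{path}: first column must be 'protein_id', got {first!r}")
    if df["protein_id"].duplicated().any():
        dupes = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()[:5]
        raise DataError(f"{path}: duplicate protein ids, e.g. {dupes}")
    return df.set_index("protein_id")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("protein_id").to_csv(path, sep="\t")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if "sample_id" not in meta.columns:
        raise DataError(f"{path}: sample metadata needs a 'sample_id' column")
    return meta.set_index("sample_id")


def read_gmt(path: str | Path) -> dict:
    """Term -> member set from a GMT file (description column ignored)."""
    sets = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"{path}:{lineno}: GMT lines need term, description, members")
        sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


STUDY_FILES = {
    "cell_counts": "cell_counts.tsv",
    "cell_meta": "cell_meta.tsv",
    "ig_counts": "ig_counts.tsv",
    "ig_meta": "ig_meta.tsv",
    "intensities": "intensities.tsv",
    "intensity_meta": "intensity_meta.tsv",
    "particles": "particles.tsv",
    "evidence": "evidence.tsv",
    "serology": "serology.tsv",
    "cdc": "cdc.tsv",
    "truth": "truth.json",
}


def write_study(proteomics: SimulatedProteomics, serology: pd.DataFrame,
                cdc: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write a complete simulated study as TSVs plus the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(proteomics.cell_counts, out / STUDY_FILES["cell_counts"])
    proteomics.cell_meta.to_csv(out / STUDY_FILES["cell_meta"], sep="\t")
    write_matrix(proteomics.ig_counts, out / STUDY_FILES["ig_counts"])
    proteomics.ig_meta.to_csv(out / STUDY_FILES["ig_meta"], sep="\t")
    write_matrix(proteomics.intensities, out / STUDY_FILES["intensities"])
    proteomics.intensity_meta.to_csv(out / STUDY_FILES["intensity_meta"], sep="\t")
    proteomics.particles.to_csv(out / STUDY_FILES["particles"], sep="\t", index=False)
    proteomics.evidence.rename_axis("gene_id").to_csv(
        out / STUDY_FILES["evidence"], sep="\t"
    )
    serology.to_csv(out / STUDY_FILES["serology"], sep="\t", index=False)
    cdc.to_csv(out / STUDY_FILES["cdc"], sep="\t", index=False)
    with open(out / STUDY_FILES["truth"], "w") as fh:
        json.dump(proteomics.truth.to_dict(), fh, indent=2)
    return out


def read_study(in_dir: str | Path) -> dict:
    """Load whatever study files are present; absent roles map to None."""
    in_dir = Path(in_dir)
    loaded: dict = {}
    readers = {
        "cell_counts": read_matrix,
        "ig_counts": read_matrix,
        "intensities": read_matrix,
        "cell_meta": read_sample_meta,
        "ig_meta": read_sample_meta,
        "intensity_meta": read_sample_meta,
        "particles": lambda p: pd.read_csv(p, sep="\t"),
        "evidence": lambda p: pd.read_csv(p, sep="\t", index_col="gene_id"),
        "serology": lambda p: pd.read_csv(p, sep="\t"),
        "cdc": lambda p: pd.read_csv(p, sep="\t"),
        "truth": lambda p: json.loads(Path(p).read_text()),
    }
    for role, filename in STUDY_FILES.items():
        path = in_dir / filename
        loaded[role] = readers[role](path) if path.exists() else None
    return loaded
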