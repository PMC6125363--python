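"""Plain-text ingest and emit: TSV tables, Skyline-style reports, Newick trees."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import to_tree

from .errors import SchemaError
from .tissue import QuantMatrix

#: default mapping from Skyline-style transition report headers to the
#: canonical long-table columns; override per-site as needed
SKYLINE_COLUMN_MAP = {
    "Replicate Name": "replicate_name",
    "Peptide Sequence": "peptide",
    "Protein Name": "protein",
    "Fragment Ion": "transition",
    "Isotope Label Type": "isotope",
    "Area": "area",
    "Retention Time": "rt",
}


#: MaxQuant-style decoy/site flag columns honored as drop rules at ingest;
#: contaminant entries are deliberately kept (keratins can be of interest)
DROP_FLAG_COLUMNS = ("Reverse", "Only identified by site")


def read_quant_matrix(matrix_path, samples_path, drop_flagged: bool = True) -> QuantMatrix:
    """Load a proteins x samples TSV plus its sample-annotation TSV.

    The annotation file needs columns ``sample, patient, region`` (and
    optionally ``compartment``); ``sample`` must match the matrix columns.
    Rows marked ``+`` in a ``Reverse`` or ``Only identified by site``
    column are dropped (decoys and site-only identifications); the flag
    columns themselves are removed from the matrix either way.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    flags = [c for c in DROP_FLAG_COLUMNS if c in values.columns]
    if flags:
        if drop_flagged:
            marked = (values[flags] == "+").any(axis=1)
            values = values.loc[~marked]
        values = values.drop(columns=flags)
        values = values.astype(float)
    samples = pd.read_csv(samples_path, sep="\t")
    if "sample" not in samples.columns:
        raise SchemaError("sample annotation must contain a 'sample' column")
    samples = samples.set_index("sample")
    try:
        samples = samples.loc[values.columns]
    except KeyError as exc:
        raise SchemaError(f"annotation missing matrix sample(s): {exc.args[0]}") from exc
    return QuantMatrix(values=values, samples=samples)


def write_quant_matrix(m: QuantMatrix, matrix_path, samples_path) -> None:
    m.values.to_csv(matrix_path, sep="\t", index_label="protein")
    m.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_transition_report(path, column_map: dict | None = None, sep: str = ",") -> pd.DataFrame:
    """Load a Skyline-style transition report into the canonical long table.

    ``column_map`` maps report headers to canonical names; additional
    columns (``patient``, ``group``) pass through unchanged. Isotope
    labels are normalized to ``light`` / ``heavy``.
    """
    raw = pd.read_csv(path, sep=sep)
    cmap = dict(SKYLINE_COLUMN_MAP if column_map is None else column_map)
    present = {k: v for k, v in cmap.items() if k in raw.columns}
    df = raw.rename(columns=present)
    required = {"patient", "group", "peptide", "transition", "isotope", "replicate", "area"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"transition report lacks columns: {sorted(missing)}")
    df["isotope"] = (
        df["isotope"].astype(str).str.lower().map({"light": "light", "heavy": "heavy"})
    )
    if df["isotope"].isna().any():
        raise SchemaError("isotope labels must normalize to 'light'/'heavy'")
    return df


def read_feature_table(path) -> tuple[pd.DataFrame, pd.Series]:
    """Load a patients x features TSV with a ``label`` column (N0/N+)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "label" not in df.columns:
        raise SchemaError("feature table must contain a 'label' column")
    labels = df.pop("label")
    return df, labels


def write_feature_table(X: pd.DataFrame, labels, path) -> None:
    out = X.copy()
    out.insert(0, "label", np.asarray(labels))
    out.to_csv(path, sep="\t", index_label="patient")


_NEWICK_SPECIAL = set(" :;,()[]'\"\t\n")


def _newick_label(label) -> str:
    label = str(label)
    if set(label) & _NEWICK_SPECIAL:
        return "'" + label.replace("'", "''") + "'"
    return label


def linkage_to_newick(merges: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths.

    Labels containing Newick metacharacters (colons in sample ids, spaces)
    are single-quoted per the format's quoting rule.
    """
    labels = list(labels)
    root = to_tree(merges)

    def _walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{_newick_label(labels[node.id])}:{length:g}"
        left = _walk(node.left, node.dist)
        right = _walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({_walk(root.left, root.dist)},{_walk(root.right, root.dist)});"


def write_run_manifest(path, config: dict, seed: int | None = None) -> None:
    """Record the run configuration, seed and library versions as JSON."""
    import prognosig

    manifest = {
        "package": "prognosig",
        "version": prognosig.__version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": config,
        "libraries": {
            name: __import__(name).__version__
            for name in ("numpy", "scipy", "pandas", "sklearn", "statsmodels")
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
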