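"""Reading and writing expression matrices, label tables and result files.

Expression matrices are plain TSV/CSV with genes as rows (first column =
gene ids, header row = sample ids); labels are a two-column table
``sample_id<TAB>class``.  All outputs are UTF-8 with LF endings and embed
the run configuration so a run can be reproduced from its own files;
nothing timestamped is written, so identical configurations produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassificationResult
from .core_scoring import ClassVector, ExpressionMatrix
from .errors import DualKSError
from .evaluation import SweepResult

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "write_results",
    "write_sweep",
    "write_error_estimate",
]


@dataclasses.dataclass
class RunConfig:
    """Options of one run, embedded into every output for provenance."""

    command: str
    variant: str | None = None
    mode: str | None = None
    t: int | None = None
    grid: list[int] | None = None
    B: int | None = None
    seed: int | None = None
    log_base: str | None = None
    stratified: bool | None = None
    allow_missing: bool | None = None
    paths: dict[str, str] | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items() if v is not None}
        d["dualks_version"] = __version__
        return d

    def header_comment(self) -> str:
        return "# config: " + json.dumps(self.to_dict(), sort_keys=True)


def _sep_for(path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if fmt not in ("tsv", "csv"):
        raise DualKSError(f"format must be 'tsv' or 'csv', got {fmt!r}")
    return "," if fmt == "csv" else "\t"


def read_expression(path, fmt: str | None = None, transpose: bool = False) -> ExpressionMatrix:
    """Load a genes x samples matrix; ``transpose`` accepts samples-as-rows files.

    Non-numeric cells and duplicate identifiers are reported explicitly
    rather than coerced.
    """
    sep = _sep_for(path, fmt)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DualKSError(f"{path}: empty expression matrix")
    if transpose:
        df = df.T
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DualKSError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise DualKSError(f"{path}: missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}")
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise DualKSError(f"{path}: duplicate gene identifiers: {', '.join(map(str, dup_genes))}")
    dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise DualKSError(f"{path}: duplicate sample identifiers: {', '.join(map(str, dup_samples))}")
    # df.astype(float) parses via float(), which is correctly rounded;
    # pd.to_numeric above is only used to locate bad cells.
    return ExpressionMatrix.from_frame(df.astype(float))


def write_expression(X: ExpressionMatrix, path, fmt: str | None = None) -> None:
    sep = _sep_for(path, fmt)
    # %.17g guarantees float64 round-trips exactly through text
    X.to_frame().rename_axis("gene_id").to_csv(
        path, sep=sep, lineterminator="\n", float_format="%.17g"
    )


def read_labels(path, sample_ids=None) -> ClassVector:
    """Load a two-column ``sample_id, class`` table.

    When ``sample_ids`` (e.g. from the expression matrix) is given, labels
    are aligned to that order by identifier; samples missing from either
    side are an error.  A ``sample_id`` header line is optional.
    """
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DualKSError(f"{path}:{lineno}: expected 2 tab-separated columns")
            rows.append((parts[0], parts[1]))
    if rows and rows[0][0] == "sample_id":
        rows = rows[1:]
    if not rows:
        raise DualKSError(f"{path}: no label rows")
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        dups = sorted({s for s in ids if ids.count(s) > 1})
        raise DualKSError(f"{path}: duplicate sample identifiers: {', '.join(dups)}")
    table = dict(rows)
    if sample_ids is not None:
        sample_ids = [str(s) for s in sample_ids]
        missing = sorted(set(sample_ids) - set(ids))
        if missing:
            raise DualKSError(f"{path}: no label for sample(s): {', '.join(missing)}")
        extra = sorted(set(ids) - set(sample_ids))
        if extra:
            raise DualKSError(f"{path}: label(s) for unknown sample(s): {', '.join(extra)}")
        labels = [table[s] for s in sample_ids]
    else:
        labels = [table[s] for s in ids]
    return ClassVector.from_labels(labels)


def write_labels(Y: ClassVector, sample_ids: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tclass\n")
        for s, y in zip(sample_ids, Y.labels):
            fh.write(f"{s}\t{y}\n")


def write_results(
    results: list[ClassificationResult],
    classes: Iterable[str],
    path,
    config: RunConfig | None = None,
) -> None:
    """Write per-sample scores and calls as TSV (one ``E_<class>`` column each)."""
    classes = list(classes)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if config is not None:
            fh.write(config.header_comment() + "\n")
        fh.write("\t".join(["sample_id", *[f"E_{c}" for c in classes], "call", "margin", "tie"]) + "\n")
        for r in results:
            cells = [r.sample_id]
            cells += [repr(r.scores[c]) for c in classes]
            cells += [r.call, repr(r.margin), "1" if r.tie else "0"]
            fh.write("\t".join(cells) + "\n")


def write_error_estimate(est, path, config: RunConfig | None = None) -> None:
    doc = est.to_dict()
    if config is not None:
        doc["config"] = config.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_sweep(
    sweep: SweepResult,
    tsv_path=None,
    json_path=None,
    config: RunConfig | None = None,
) -> None:
    """Write the grid table (TSV) and/or a JSON summary with the optimum."""
    if tsv_path is not None:
        with open(tsv_path, "w", encoding="utf-8", newline="\n") as fh:
            if config is not None:
                fh.write(config.header_comment() + "\n")
            fh.write("t\tvariant\terr_train\terr_loo_boot\tgamma\terr_632plus\n")
            for t in sweep.grid:
                for v in sweep.variants:
                    e = sweep.estimates[(t, v)]
                    fh.write(
                        f"{t}\t{v}\t{e.err_train!r}\t{e.err_loo_boot!r}"
                        f"\t{e.gamma!r}\t{e.err_632plus!r}\n"
                    )
    if json_path is not None:
        doc = {
            "grid": sweep.grid,
            "variants": sweep.variants,
            "optimum_t": sweep.optimum_t,
            "optimum_variant": sweep.optimum_variant,
            "optimum_err_632plus": sweep.optimum_error,
            "estimates": [
                {"t": t, "variant": v, **sweep.estimates[(t, v)].to_dict()}
                for t in sweep.grid
                for v in sweep.variants
            ],
        }
        if config is not None:
            doc["config"] = config.to_dict()
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
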