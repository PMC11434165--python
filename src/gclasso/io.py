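"""Delimited-text readers and writers.

Designs are plain CSV/TSV (delimiter inferred from the extension): first
row is a header of predictor names, optional first column of sample IDs,
response either as a named column or a separate single-column file.  Graphs
are 2- or 3-column edge lists (``u  v  [weight]``); missing weights mean 1,
``#`` lines are comments.  Results go out as a TSV whose ``#`` header
records the full run configuration, so a run is reproducible from its
output alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .graphs import PredictorGraph
from .inference import InferenceResult
from .penalized import RegressionData

log = logging.getLogger("gclasso")

__all__ = ["read_matrix", "read_graph", "write_results", "read_results"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path: str | Path,
    response: str | Path | None = None,
    *,
    index_col: bool = True,
    standardize: bool = False,
) -> RegressionData:
    """Read a design (and response) from delimited text.

    ``response`` is either the name of a column of the design file or the
    path of a separate one-column file.  Non-numeric cells and missing
    values are reported with their location.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#",
                     index_col=0 if index_col else None)
    y = None
    if response is not None and str(response) in df.columns:
        y = df.pop(str(response)).to_numpy()
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise InputError(
            f"{path.name}: non-numeric cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}")
    if num.isna().any().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise InputError(
            f"{path.name}: missing value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}")
    if y is None:
        if response is None:
            raise InputError("no response column or file given")
        rpath = Path(response)
        if not rpath.exists():
            raise InputError(
                f"response {response!r} is neither a column of "
                f"{path.name} nor a file")
        ys = pd.read_csv(rpath, sep=_sep_for(rpath), comment="#",
                         index_col=0 if index_col else None)
        y = ys.iloc[:, 0].to_numpy()
    y = pd.to_numeric(pd.Series(y), errors="coerce").to_numpy()
    if np.isnan(y).any():
        raise InputError("response contains missing or non-numeric values")
    data = RegressionData.from_arrays(num.to_numpy(float), y,
                                      labels=list(num.columns),
                                      standardize=standardize)
    log.info("read design %s: n=%d, p=%d", path.name, data.n, data.p)
    return data


def read_graph(path: str | Path, node_labels: list[str]) -> PredictorGraph:
    """Read an edge list restricted to the given predictor labels.

    Edges whose endpoints are not all known are dropped with a warning
    (pathway exports routinely contain genes absent from the expression
    panel); if *no* edge matches a non-empty edge list, that is an error.
    Duplicate edges have their weights summed.
    """
    path = Path(path)
    known = set(node_labels)
    edges, dropped, n_rows = [], 0, 0
    seen = set()
    dup_warned = False
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) not in (2, 3):
                raise InputError(
                    f"{path.name}:{line_no}: expected 2 or 3 fields, "
                    f"got {len(parts)}")
            u, v = parts[0], parts[1]
            # tolerate a header row
            if n_rows == 0 and (u not in known and v not in known) \
                    and len(parts) == 3 and not _is_number(parts[2]):
                continue
            n_rows += 1
            if u not in known or v not in known:
                dropped += 1
                continue
            key = frozenset((u, v))
            if key in seen and not dup_warned:
                log.warning("%s: duplicate edges found; weights summed",
                            path.name)
                dup_warned = True
            seen.add(key)
            if len(parts) == 3:
                if not _is_number(parts[2]):
                    raise InputError(
                        f"{path.name}:{line_no}: non-numeric weight "
                        f"{parts[2]!r}")
                edges.append((u, v, float(parts[2])))
            else:
                edges.append((u, v))
    if n_rows > 0 and not edges:
        raise InputError(
            f"{path.name}: no edge matches the {len(known)} predictor labels")
    if dropped:
        log.warning("%s: dropped %d edges with unknown endpoints",
                    path.name, dropped)
    if n_rows == 0:
        log.warning("%s: empty edge list; inference degrades to a diagonal "
                    "precision surrogate", path.name)
    return PredictorGraph.from_edges(node_labels, edges)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_results(result: InferenceResult, path: str | Path,
                  labels: list[str] | None = None,
                  gene_alpha: float | None = None) -> None:
    """Write the per-coordinate results table with a provenance header."""
    path = Path(path)
    p = result.b_hat.shape[0]
    labels = labels or [f"x{j + 1}" for j in range(p)]
    thr = gene_alpha if gene_alpha is not None else result.alpha
    df = pd.DataFrame({
        "predictor": labels,
        "beta_init": result.beta_init if result.beta_init is not None
        else np.full(p, np.nan),
        "b_debiased": result.b_hat,
        "se": result.se,
        "ci_lower": result.ci_lower,
        "ci_upper": result.ci_upper,
        "p_value": result.p_values,
        "significant_at_gene_alpha": result.p_values < thr,
    })
    with open(path, "w") as fh:
        fh.write(f"# method={result.method} alpha={result.alpha!r} "
                 f"sigma_sq={result.sigma_sq!r}\n")
        if gene_alpha is not None:
            fh.write(f"# gene_alpha={gene_alpha!r}\n")
        if result.T_n is not None:
            fh.write(f"# T_n={result.T_n!r} C_alpha={result.C_alpha!r} "
                     f"global_reject={result.global_reject}\n")
        for k, v in result.provenance.items():
            fh.write(f"# {k}={v!r}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def export_theta(theta, path: str | Path, fmt: str = "dense") -> None:
    """Write the precision surrogate as delimited text for debugging.

    ``fmt="dense"`` writes the full p x p matrix as TSV; ``fmt="triplet"``
    writes rows ``i<TAB>j<TAB>value`` for the nonzero entries only (the
    natural choice for sparse pathway graphs).
    """
    T = theta.Theta_hat if hasattr(theta, "Theta_hat") else np.asarray(theta)
    path = Path(path)
    if fmt == "dense":
        np.savetxt(path, T, delimiter="\t", fmt="%.17g")
    elif fmt == "triplet":
        with open(path, "w") as fh:
            fh.write("i\tj\tvalue\n")
            for i, j in zip(*np.nonzero(T)):
                fh.write(f"{i}\t{j}\t{T[i, j]:.17g}\n")
    else:
        raise InputError(f"unknown format {fmt!r}")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results table (header comments ignored)."""
    return pd.read_csv(path, sep="\t", comment="#",
                       float_precision="round_trip")
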