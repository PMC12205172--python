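"""Readers/writers for matrices, labels, couplings, and run configuration.

All indices in output files are 0-based; matrices are dense TSV by
default with MatrixMarket (MTX) supported for sparse data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix, issparse

from .manifold import ModalityData
from .selfalign import Coupling

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_coupling",
    "write_coupling",
    "RunConfig",
]


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "csv", "mtx", "txt"):
        return "tsv" if suffix == "txt" else suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def read_matrix(
    path: str | Path,
    fmt: str | None = None,
    ids: bool | str | Path = False,
    labels: str | Path | None = None,
) -> ModalityData:
    """Load a cells x features matrix as :class:`ModalityData`.

    ``ids=True`` treats the first TSV/CSV column as cell identifiers; for
    MTX, ``ids`` may be a path to a one-ID-per-line file.  NaN/Inf are
    rejected with the offending location named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input matrix not found: {path}")
    fmt = _detect_format(path, fmt)
    cell_ids = None
    if fmt == "mtx":
        m = mmread(str(path))
        mat = np.asarray(m.todense() if issparse(m) else m, dtype=float)
        if isinstance(ids, (str, Path)):
            cell_ids = read_labels(ids).tolist()
    elif fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, header=None, index_col=0 if ids is True else None)
        except pd.errors.ParserError as exc:
            raise ValueError(f"parse error in {path.name}: {exc}") from exc
        if ids is True:
            cell_ids = [str(v) for v in df.index]
        mat = df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    lab = read_labels(labels) if labels is not None else None
    return ModalityData(mat, cell_ids=cell_ids, labels=lab)


def write_matrix(
    matrix: np.ndarray | ModalityData,
    path: str | Path,
    fmt: str | None = None,
    sparse_threshold: float = 0.9,
) -> Path:
    """Write a matrix as dense TSV (or MTX when very sparse or requested)."""
    path = Path(path)
    arr = matrix.matrix if isinstance(matrix, ModalityData) else np.asarray(matrix)
    fmt = _detect_format(path, fmt)
    if fmt == "mtx" or (
        fmt is None and (arr == 0).mean() > sparse_threshold
    ):
        mmwrite(str(path.with_suffix(".mtx")), coo_matrix(arr))
        return path.with_suffix(".mtx")
    sep = "," if fmt == "csv" else "\t"
    np.savetxt(path, arr, delimiter=sep, fmt="%.12g")
    return path


def read_labels(path: str | Path) -> np.ndarray:
    """One label per line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    return np.asarray([line.strip() for line in path.read_text().splitlines() if line.strip() != ""])


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(str(v) for v in labels) + "\n")
    return path


def write_coupling(coupling: Coupling, path: str | Path) -> Path:
    """Dense TSV plus a metadata sidecar JSON (<name>.meta.json)."""
    path = Path(path)
    np.savetxt(path, coupling.gamma, delimiter="\t", fmt="%.12g")
    meta = {
        "row_marginal": coupling.row_marginal.tolist(),
        "col_marginal": coupling.col_marginal.tolist(),
        "epsilon": None if np.isnan(coupling.epsilon) else coupling.epsilon,
        "objective": None if np.isnan(coupling.objective) else coupling.objective,
        "converged": bool(coupling.converged),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_coupling(path: str | Path, fmt: str | None = None) -> Coupling:
    """Load a coupling from TSV/MTX; marginals from the sidecar if present."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "mtx":
        gamma = np.asarray(mmread(str(path)).todense(), dtype=float)
    else:
        gamma = np.loadtxt(path, delimiter="\t" if fmt == "tsv" else ",")
    gamma = np.atleast_2d(gamma)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        p = np.asarray(meta["row_marginal"])
        q = np.asarray(meta["col_marginal"])
        eps = meta.get("epsilon")
        obj = meta.get("objective")
        return Coupling(
            gamma,
            p,
            q,
            objective=np.nan if obj is None else obj,
            converged=meta.get("converged", True),
            epsilon=np.nan if eps is None else eps,
        )
    return Coupling(gamma, gamma.sum(axis=1), gamma.sum(axis=0))


@dataclass
class RunConfig:
    """All pipeline tunables; serializable to/from YAML.

    A resolved copy is written beside every run's outputs so any run can
    be reproduced bit-for-bit from its output directory.
    """

    data_x: str | None = None
    data_y: str | None = None
    coupling_xy: str | None = None
    labels_x: str | None = None
    labels_y: str | None = None
    out_dir: str = "sonata_out"
    # manifold / self-alignment
    n_replicates: int = 20
    noise_sd: float = 0.1
    k_schedule: list[int] | None = None
    source_k: int | None = None
    epsilon: float = 5e-3
    # ambiguity statistics
    alpha: float = 0.01
    local_quantile: float = 0.20
    min_fold_change: float = 2.0
    ambiguous_fraction_threshold: float | None = None  # default: 2 * alpha
    # grouping
    kmax: int = 8
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ambiguous_fraction_threshold is None:
            self.ambiguous_fraction_threshold = 2 * self.alpha

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)
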