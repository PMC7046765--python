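"""File I/O, configuration and the end-to-end pipeline.

Cell tables travel as CSV/TSV (canonical) with one row per cell: a
``cell_id`` column, a pseudotime column in [0, 1], and marker columns.
FCS flow-cytometry files are readable when the optional ``fcsparser``
dependency is installed.  Every output file starts with comment lines
recording the package version, the config hash and the seed, so a run
can be traced back to its inputs.

``run_pipeline`` ties the stages together: read + validate cells,
estimate the pseudotime density (reflecting or linked boundary), build
the measure-preserving map from the configured prior, push the per-marker
joint densities onto the real scale, and write densities, the s->x map
table and trajectory summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import densities as dens
from . import transform as tfm
from .priors import RealScalePrior, prior_from_config

__all__ = [
    "CellTable",
    "RunConfig",
    "read_cells",
    "write_cells",
    "subsample_cells",
    "run_pipeline",
    "read_config",
    "write_table",
    "read_table",
]

logger = logging.getLogger("truescale")

#: default number of cells retained for pseudotime analysis
DEFAULT_SUBSAMPLE = 10_000


@dataclasses.dataclass
class CellTable:
    """A validated per-cell table: ids, pseudotime and marker channels."""

    frame: pd.DataFrame
    pseudotime_col: str = "s"
    marker_cols: tuple[str, ...] = ()
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.frame
        if self.pseudotime_col not in f.columns:
            raise ValueError(f"missing pseudotime column {self.pseudotime_col!r}")
        for c in self.marker_cols:
            if c not in f.columns:
                raise ValueError(f"missing marker column {c!r}")
        if "cell_id" in f.columns and f["cell_id"].duplicated().any():
            dup = f.loc[f["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValueError(f"duplicate cell_id {dup!r}")
        s = f[self.pseudotime_col]
        bad = s[(s < 0) | (s > 1) | s.isna()]
        if len(bad):
            rows = bad.index[:5].tolist()
            raise ValueError(
                f"pseudotime outside [0, 1] (or NaN) in rows {rows}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.frame)

    def sample(self, channel: str) -> dens.PseudotimeSample:
        return dens.PseudotimeSample(
            s=self.frame[self.pseudotime_col].to_numpy(dtype=float),
            y=self.frame[channel].to_numpy(dtype=float),
            cell_id=self.frame["cell_id"].to_numpy()
            if "cell_id" in self.frame.columns
            else None,
        )


def read_cells(
    path,
    format: str | None = None,
    pseudotime_col: str = "s",
    marker_cols: tuple[str, ...] | list[str] = (),
    channel_map: dict | None = None,
) -> CellTable:
    """Read and validate a cell table from CSV, TSV or FCS.

    Rows with NaN in the pseudotime or any requested marker column are
    dropped with a logged count (dead cells / doublets are assumed to
    have been gated out upstream).
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".fcs": "fcs"}.get(path.suffix.lower(), "csv")
    if format == "csv":
        frame = pd.read_csv(path, comment="#")
    elif format == "tsv":
        frame = pd.read_csv(path, sep="\t", comment="#")
    elif format == "fcs":
        try:
            import fcsparser  # soft optional dependency
        except ImportError as exc:
            raise ImportError(
                "FCS support requires the optional 'fcsparser' package "
                "(pip install truescale[fcs]); alternatively export the "
                "acquisition to CSV"
            ) from exc
        _meta, frame = fcsparser.parse(str(path), reformat_meta=True)
        if channel_map:
            frame = frame.rename(columns=channel_map)
        frame = frame.reset_index(drop=True)
        if "cell_id" not in frame.columns:
            frame.insert(0, "cell_id", np.arange(len(frame)))
    else:
        raise ValueError(f"unknown format {format!r}")

    used = [pseudotime_col, *marker_cols]
    missing = [c for c in used if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns {missing} in {path.name}")
    n0 = len(frame)
    frame = frame.dropna(subset=used).reset_index(drop=True)
    if len(frame) < n0:
        logger.info("dropped %d rows with NaN in used columns", n0 - len(frame))
    return CellTable(
        frame=frame,
        pseudotime_col=pseudotime_col,
        marker_cols=tuple(marker_cols),
        metadata={"source": str(path), "format": format},
    )


def write_cells(table: CellTable, path, header: dict | None = None) -> None:
    """Write a cell table to CSV with provenance comment lines."""
    _write_with_header(table.frame, path, header or {})


def subsample_cells(
    table: CellTable,
    n: int = DEFAULT_SUBSAMPLE,
    seed: int | np.random.Generator = 0,
    allow_all: bool = False,
) -> CellTable:
    """Uniform random subsample of ``n`` cells without replacement."""
    if n > table.n_cells:
        if not allow_all:
            raise ValueError(
                f"requested {n} cells but only {table.n_cells} available "
                "(pass allow_all=True to keep everything)"
            )
        n = table.n_cells
    rng = np.random.default_rng(seed)
    idx = rng.choice(table.n_cells, size=n, replace=False)
    return CellTable(
        frame=table.frame.iloc[idx].reset_index(drop=True),
        pseudotime_col=table.pseudotime_col,
        marker_cols=table.marker_cols,
        metadata=dict(table.metadata, subsampled_to=n),
    )


# --------------------------------------------------------------------------
# configuration

_KNOWN_KEYS = {
    "input", "pseudotime_col", "marker_cols", "log_markers", "prior",
    "boundary", "grid_points_s", "grid_points_y", "bandwidth_s",
    "bandwidth_y", "quantiles", "normalize_surface_um", "subsample",
    "seed", "out_prefix",
}
_KNOWN_PRIOR_TYPES = {"age", "spheroid", "spheroid_from_growth", "empirical"}


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``prior`` follows the schema of :func:`truescale.priors.prior_from_config`;
    ``boundary`` selects the pseudotime KDE ('reflecting' or 'linked');
    ``log_markers`` lists channels to density-estimate on log10 intensity;
    ``normalize_surface_um``, when set, rescales markers to the median of
    cells within that depth of the spheroid surface.
    """

    input: str | None
    prior: dict
    pseudotime_col: str = "s"
    marker_cols: tuple[str, ...] = ()
    log_markers: tuple[str, ...] = ()
    boundary: str = "reflecting"
    grid_points_s: int = dens.GRID_POINTS_S
    grid_points_y: int = dens.GRID_POINTS_Y
    bandwidth_s: float | None = None
    bandwidth_y: float | None = None
    quantiles: tuple[float, ...] = (0.25, 0.5, 0.75)
    normalize_surface_um: float | None = None
    subsample: int | None = None
    seed: int = 0
    out_prefix: str = "truescale_run"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "prior" not in raw:
            raise ValueError("config must specify a prior")
        ptype = raw["prior"].get("type")
        if ptype not in _KNOWN_PRIOR_TYPES:
            raise ValueError(
                f"unknown prior type {ptype!r}; expected one of "
                f"{sorted(_KNOWN_PRIOR_TYPES)}"
            )
        if raw.get("boundary", "reflecting") not in ("reflecting", "linked"):
            raise ValueError("boundary must be 'reflecting' or 'linked'")
        kwargs = dict(raw)
        for key in ("marker_cols", "log_markers", "quantiles"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(input=kwargs.pop("input", None), **kwargs)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_config(path) -> RunConfig:
    """Load a YAML or JSON config file and validate it."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    return RunConfig.from_dict(raw)


# --------------------------------------------------------------------------
# output plumbing


def _write_with_header(frame: pd.DataFrame, path, header: dict) -> None:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        frame.to_csv(fh, index=False)


def write_table(frame: pd.DataFrame, path, config_hash: str = "", seed=None) -> None:
    """CSV with provenance header (config hash and seed)."""
    from . import __version__

    _write_with_header(
        frame, path,
        {"truescale_version": __version__, "config_hash": config_hash, "seed": seed},
    )


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def density_to_frame(d: dens.Density1D) -> pd.DataFrame:
    return pd.DataFrame({"grid": d.grid, "p": d.p})


def joint_to_frame(d: dens.JointDensity2D) -> pd.DataFrame:
    """Long-format (x, y, p) serialization of a 2-D density."""
    xx, yy = np.meshgrid(d.grid_s, d.grid_y, indexing="ij")
    return pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(), "p": d.p.ravel()})


def joint_from_frame(frame: pd.DataFrame) -> dens.JointDensity2D:
    gx = np.unique(frame["x"].to_numpy())
    gy = np.unique(frame["y"].to_numpy())
    p = frame["p"].to_numpy().reshape(gx.size, gy.size)
    return dens.JointDensity2D(gx, gy, p)


# --------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig, table: CellTable | None = None) -> dict:
    """Run the full snapshot-to-real-scale reconstruction.

    Returns a dict of output file paths; all numeric outputs are written
    as CSV under ``config.out_prefix``.  Any stage failure raises with a
    stage-labelled message.
    """
    out = {}
    prefix = pathlib.Path(config.out_prefix)
    h = config.hash()

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        name = stage("read")
        if table is None:
            if config.input is None:
                raise ValueError("config has no input file and no table was passed")
            table = read_cells(
                config.input,
                pseudotime_col=config.pseudotime_col,
                marker_cols=config.marker_cols,
            )
        if config.subsample is not None:
            table = subsample_cells(table, config.subsample, seed=config.seed,
                                    allow_all=True)

        name = stage("prior")
        prior: RealScalePrior = prior_from_config(config.prior)

        name = stage("pseudotime-density")
        s = table.frame[config.pseudotime_col].to_numpy(dtype=float)
        h_s = config.bandwidth_s or dens.silverman_bandwidth(s)
        grid_s = np.linspace(0.0, 1.0, config.grid_points_s)
        kde = dens.kde_linked if config.boundary == "linked" else dens.kde_reflecting
        p_s = kde(s, h_s, grid_s)
        write_table(density_to_frame(p_s), f"{prefix}.density_s.csv",
                    h, config.seed)
        out["density_s"] = str(f"{prefix}.density_s.csv")

        name = stage("map")
        tmap = tfm.build_map(p_s, prior)
        map_frame = pd.DataFrame(
            {"s": tmap.s_grid, "x": tmap.x_grid, "P_s": tmap.source_cdf}
        )
        write_table(map_frame, f"{prefix}.map.csv", h, config.seed)
        out["map"] = str(f"{prefix}.map.csv")

        p_x = tfm.transform_density(p_s, tmap)
        write_table(density_to_frame(p_x), f"{prefix}.density_x.csv",
                    h, config.seed)
        out["density_x"] = str(f"{prefix}.density_x.csv")

        name = stage("markers")
        depths = None
        if config.normalize_surface_um is not None:
            depths = np.asarray(tmap.forward(s))
        for channel in config.marker_cols:
            y = table.frame[channel].to_numpy(dtype=float)
            if depths is not None:
                y = tfm.normalize_to_surface_median(
                    y, depths, cutoff=config.normalize_surface_um
                )
            log_y = channel in config.log_markers
            yk = np.log10(y) if log_y else y
            h_y = config.bandwidth_y or dens.silverman_bandwidth(yk)
            sample = dens.PseudotimeSample(s=s, y=y)
            joint = dens.kde_joint(
                sample,
                dens.Bandwidths(h_s, h_y),
                grid_s=grid_s,
                grid_y=np.linspace(
                    yk.min() - 3 * h_y, yk.max() + 3 * h_y, config.grid_points_y
                ),
                boundary=config.boundary,
                log_scale_y=log_y,
            )
            joint_x = tfm.transform_joint(joint, tmap)
            cond = tfm.conditional_density(joint_x)
            summ = tfm.trajectory_summary(cond, config.quantiles)
            base = f"{prefix}.{channel}"
            write_table(joint_to_frame(joint_x), f"{base}.joint_x.csv", h, config.seed)
            qcols = {f"q{q:g}": summ.curves[i] for i, q in enumerate(summ.quantiles)}
            write_table(
                pd.DataFrame({"x": summ.grid_x, "valid": cond.valid, **qcols}),
                f"{base}.summary.csv", h, config.seed,
            )
            out[f"joint_x:{channel}"] = f"{base}.joint_x.csv"
            out[f"summary:{channel}"] = f"{base}.summary.csv"
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {name!r}: {exc}") from exc

    logger.info("pipeline finished: %d artifacts", len(out))
    return out
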