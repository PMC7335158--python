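"""Plain-text file formats and run configuration.

Formats are deliberately simple, dense text: tab-separated square matrices
with ``#``-comment headers carrying genomic metadata, per-molecule XYZ
blocks for conformations, bedGraph tracks, and BED-like boundary calls.
Genomic coordinates are 0-based, half-open throughout; round trips are exact
to numeric tolerance 1e-9.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Conformation, Ensemble, PolymerModel, SimulationParams
from .metrics import DistanceMatrix
from .prismr import ContactMatrix

__all__ = [
    "read_contact_matrix",
    "write_contact_matrix",
    "read_distance_matrices",
    "write_distance_matrices",
    "read_conformations",
    "write_conformations",
    "read_track",
    "write_track",
    "write_boundary_calls",
    "write_model",
    "read_model",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def _write_header(fh, meta: dict) -> None:
    for k, v in meta.items():
        fh.write(f"# {k}={v}\n")


def _read_header(path: Path) -> tuple[dict, int]:
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta, skip


def _read_dense(path: Path, skip: int) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if ln <= skip or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                rows.append([float(x) if x.strip() != "" else np.nan for x in fields])
            except ValueError as err:
                raise ValueError(f"{path}: bad numeric value on line {ln}") from err
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    width = len(rows[0])
    for k, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(f"{path}: ragged row on line {skip + k + 1}")
    return np.asarray(rows, dtype=float)


def write_contact_matrix(path, cm: ContactMatrix) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(
            fh,
            {
                "format": "sbsphase-contact-matrix",
                "chrom": cm.chrom,
                "origin_bp": cm.origin_bp,
                "resolution_bp": cm.resolution_bp,
                "normalization": cm.normalization,
            },
        )
        np.savetxt(fh, cm.values, delimiter="\t", fmt="%.10g")


def read_contact_matrix(path) -> ContactMatrix:
    path = Path(path)
    meta, skip = _read_header(path)
    vals = _read_dense(path, skip)
    if np.isnan(vals).any():
        raise ValueError(f"{path}: NaN not allowed in contact matrices")
    if np.abs(vals - vals.T).max() > 1e-9:
        raise ValueError(f"{path}: matrix not symmetric (tol 1e-9)")
    return ContactMatrix(
        values=vals,
        resolution_bp=int(meta.get("resolution_bp", 30_000)),
        origin_bp=int(meta.get("origin_bp", 0)),
        chrom=meta.get("chrom", "chrS"),
        normalization=meta.get("normalization", "raw"),
    )


def write_distance_matrices(path, matrices: list[DistanceMatrix]) -> None:
    """All single-molecule distance matrices of one ensemble in one file."""
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(
            fh,
            {
                "format": "sbsphase-distance-matrices",
                "n_matrices": len(matrices),
                "units": matrices[0].units if matrices else "sigma",
                "origin_bp": matrices[0].origin_bp if matrices else 0,
                "resolution_bp": matrices[0].resolution_bp if matrices else 30_000,
            },
        )
        for k, m in enumerate(matrices):
            fh.write(f"## matrix {k}\n")
            np.savetxt(fh, m.values, delimiter="\t", fmt="%.10g")


def read_distance_matrices(path) -> list[DistanceMatrix]:
    path = Path(path)
    meta, _ = _read_header(path)
    units = meta.get("units", "sigma")
    res = int(meta.get("resolution_bp", 30_000))
    origin = int(meta.get("origin_bp", 0))
    out: list[DistanceMatrix] = []
    rows: list[list[float]] = []

    def flush():
        if rows:
            arr = np.asarray(rows, dtype=float)
            out.append(
                DistanceMatrix(
                    values=arr, units=units, resolution_bp=res, origin_bp=origin
                )
            )
            rows.clear()

    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("##"):
                flush()
            elif line.startswith("#") or not line.strip():
                continue
            else:
                fields = line.rstrip("\n").split("\t")
                vals = []
                for x in fields:
                    tok = x.strip().lower()
                    vals.append(np.nan if tok in ("", "nan", "na") else float(x))
                if rows and len(vals) != len(rows[0]):
                    raise ValueError(f"{path}: ragged row on line {ln}")
                rows.append(vals)
    flush()
    return out


# ---------------------------------------------------------------------------
# conformations
# ---------------------------------------------------------------------------


def write_conformations(path, ens: Ensemble) -> None:
    """Per-molecule XYZ blocks (bead index, x, y, z in sigma units)."""
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(
            fh,
            {
                "format": "sbsphase-conformations",
                "n_molecules": len(ens),
                "state_label": ens.state_label,
                "model_n": ens.model.n,
                "model_r": ens.model.r,
                "resolution_bp": ens.model.resolution_bp,
                "origin_bp": ens.model.origin_bp,
                "model_colors": ",".join(map(str, ens.model.colors.tolist())),
                "params": json.dumps(
                    {
                        k: v
                        for k, v in dataclasses.asdict(ens.params).items()
                        if isinstance(v, (int, float, str, type(None)))
                    }
                ),
            },
        )
        for k, conf in enumerate(ens.conformations):
            fh.write(f"## conformation {k} time_stamp={conf.time_stamp}\n")
            for b, (x, y, z) in enumerate(conf.coords):
                fh.write(f"{b}\t{x:.9g}\t{y:.9g}\t{z:.9g}\n")


def read_conformations(path) -> Ensemble:
    path = Path(path)
    meta, _ = _read_header(path)
    colors = np.array([int(v) for v in meta["model_colors"].split(",")])
    model = PolymerModel(
        colors=colors,
        n=int(meta.get("model_n", colors.max(initial=0))),
        r=int(meta.get("model_r", 1)),
        resolution_bp=int(meta.get("resolution_bp", 30_000)),
        origin_bp=int(meta.get("origin_bp", 0)),
    )
    pdict = json.loads(meta.get("params", "{}"))
    valid = {f.name for f in dataclasses.fields(SimulationParams)}
    params = SimulationParams(**{k: v for k, v in pdict.items() if k in valid})
    confs: list[Conformation] = []
    coords: list[list[float]] = []
    stamp = 0

    def flush():
        nonlocal coords
        if coords:
            confs.append(Conformation(coords=np.asarray(coords), time_stamp=stamp))
            coords = []

    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                flush()
                stamp = int(line.rsplit("time_stamp=", 1)[1])
            elif line.startswith("#") or not line.strip():
                continue
            else:
                fields = line.split("\t")
                coords.append([float(fields[1]), float(fields[2]), float(fields[3])])
    flush()
    return Ensemble(
        conformations=confs,
        params=params,
        model=model,
        state_label=meta.get("state_label", "unlabeled"),
    )


# ---------------------------------------------------------------------------
# tracks and calls
# ---------------------------------------------------------------------------


def write_track(
    path, values, chrom: str = "chrS", origin_bp: int = 0, resolution_bp: int = 30_000
) -> None:
    """Per-window values as a bedGraph (0-based, half-open intervals)."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        for w, v in enumerate(values):
            start = origin_bp + w * resolution_bp
            fh.write(f"{chrom}\t{start}\t{start + resolution_bp}\t{v:.10g}\n")


def read_track(
    path, n_windows: int, origin_bp: int = 0, resolution_bp: int = 30_000
) -> np.ndarray:
    """Bin a bedGraph onto windows: index = floor((pos - origin)/resolution).

    Interval values are distributed over the covered windows proportionally
    to overlap length (a record aligned to one bin contributes exactly its
    value to that bin).
    """
    out = np.zeros(n_windows)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
    )
    for _, rec in df.iterrows():
        s, e, v = int(rec.start), int(rec.end), float(rec.value)
        w0 = (s - origin_bp) // resolution_bp
        w1 = (e - 1 - origin_bp) // resolution_bp
        for w in range(max(w0, 0), min(w1, n_windows - 1) + 1):
            bin_s = origin_bp + w * resolution_bp
            bin_e = bin_s + resolution_bp
            ov = min(e, bin_e) - max(s, bin_s)
            if ov > 0:
                out[w] += v * ov / resolution_bp
    return out


def write_boundary_calls(
    path, calls, strengths, chrom="chrS", origin_bp=0, resolution_bp=30_000
) -> None:
    with open(path, "w") as fh:
        for w, s in zip(calls, strengths):
            start = origin_bp + int(w) * resolution_bp
            fh.write(f"{chrom}\t{start}\t{start + resolution_bp}\t{s:.6g}\n")


def write_model(prefix, model: PolymerModel) -> list[Path]:
    """Flat colors file plus one bedGraph-like track per specific color."""
    prefix = Path(prefix)
    out = []
    flat = prefix.with_suffix(".colors.txt")
    with open(flat, "w") as fh:
        _write_header(
            fh,
            {
                "format": "sbsphase-coloring",
                "n": model.n,
                "r": model.r,
                "chrom": model.chrom,
                "origin_bp": model.origin_bp,
                "resolution_bp": model.resolution_bp,
            },
        )
        fh.write("\n".join(map(str, model.colors.tolist())) + "\n")
    out.append(flat)
    counts = model.color_counts()
    for c in range(1, model.n + 1):
        p = prefix.parent / f"{prefix.name}.color{c}.bedgraph"
        write_track(
            p,
            counts[:, c],
            chrom=model.chrom,
            origin_bp=model.origin_bp,
            resolution_bp=model.resolution_bp,
        )
        out.append(p)
    return out


def read_model(flat_path) -> PolymerModel:
    meta, skip = _read_header(Path(flat_path))
    colors = np.loadtxt(flat_path, dtype=int, skiprows=skip)
    return PolymerModel(
        colors=np.atleast_1d(colors),
        n=int(meta["n"]),
        r=int(meta.get("r", 1)),
        resolution_bp=int(meta.get("resolution_bp", 30_000)),
        origin_bp=int(meta.get("origin_bp", 0)),
        chrom=meta.get("chrom", "chrS"),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Serializable stage parameters; written next to every run's outputs."""

    stage: str = ""
    seed: int = 0
    out_dir: str = "."
    params: dict = dataclasses.field(default_factory=dict)

    def save(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["written"] = datetime.datetime.now().isoformat(timespec="seconds")
        doc["package"] = "sbsphase"
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.pop("written", None)
        doc.pop("package", None)
        return cls(**doc)
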