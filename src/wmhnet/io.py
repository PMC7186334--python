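"""Readers and writers for the pipeline's on-disk formats.

* connectivity matrices — TSV with a node-name header row and column;
* cohort tables — CSV, one row per subject;
* streamlines — plain text, one ``x y z`` point per line, blank line
  between streamlines;
* volumes (direction fields, FA maps, label masks) — NIfTI via nibabel.

Matrix readers validate shape, symmetry, and the zero diagonal and name
the offending entry on failure, so indexing conventions never leak past
the file boundary.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectome import Connectome, Parcellation
from .metrics import WeightedGraph
from .tracking import DirectionField, Streamline


class FormatError(ValueError):
    """A file failed structural validation."""


# -- matrices ---------------------------------------------------------------

def write_matrix_tsv(path, matrix: np.ndarray, node_names) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(node_names),
                      columns=list(node_names))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path, require_symmetric: bool = True):
    """Returns ``(matrix, node_names)`` after structural validation."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels disagree")
    M = df.to_numpy(dtype=float)
    if require_symmetric:
        if not np.allclose(M, M.T, atol=1e-9):
            i, j = np.unravel_index(np.argmax(np.abs(M - M.T)), M.shape)
            raise FormatError(
                f"{path}: matrix not symmetric at row {df.index[i]!r} / "
                f"column {df.columns[j]!r}")
        bad = np.nonzero(np.diag(M))[0]
        if bad.size:
            raise FormatError(
                f"{path}: nonzero diagonal at node {df.index[bad[0]]!r}")
    return M, list(df.index)


def write_connectome(prefix, connectome: Connectome) -> None:
    """Write ``<prefix>.fn.tsv``, ``.fa.tsv``, ``.length.tsv``."""
    prefix = str(prefix)
    write_matrix_tsv(prefix + ".fn.tsv", connectome.fn, connectome.node_names)
    write_matrix_tsv(prefix + ".fa.tsv", connectome.fa_mean,
                     connectome.node_names)
    write_matrix_tsv(prefix + ".length.tsv", connectome.length_mean,
                     connectome.node_names)


def read_connectome(prefix) -> Connectome:
    prefix = str(prefix)
    fn, names = read_matrix_tsv(prefix + ".fn.tsv")
    fa, names_fa = read_matrix_tsv(prefix + ".fa.tsv")
    ln, names_ln = read_matrix_tsv(prefix + ".length.tsv")
    if names_fa != names or names_ln != names:
        raise FormatError(f"{prefix}: node labels differ across matrices")
    return Connectome(node_names=names, fn=fn, fa_mean=fa, length_mean=ln)


def write_weighted_graph(path, graph: WeightedGraph) -> None:
    write_matrix_tsv(path, graph.weights, graph.node_names)


def read_weighted_graph(path) -> WeightedGraph:
    M, names = read_matrix_tsv(path)
    return WeightedGraph(weights=M, node_names=names)


# -- cohort tables ----------------------------------------------------------

def write_cohort_csv(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False, float_format="%.10g")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


# -- streamlines ------------------------------------------------------------

def write_streamlines(path, streamlines) -> None:
    with open(path, "w") as fh:
        for s, sl in enumerate(streamlines):
            if s:
                fh.write("\n")
            for p in sl.points:
                fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")


def read_streamlines(path) -> list[Streamline]:
    streamlines, current = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                if current:
                    streamlines.append(Streamline(points=np.array(current)))
                    current = []
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}: bad streamline point {line!r}")
            current.append([float(v) for v in parts])
    if current:
        streamlines.append(Streamline(points=np.array(current)))
    return streamlines


# -- NIfTI volumes ----------------------------------------------------------

def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_direction_field(prefix, field: DirectionField) -> None:
    """Write ``<prefix>.dirs.nii.gz`` (4-D) and ``<prefix>.fa.nii.gz``."""
    aff = _affine(field.voxel_size)
    nib.save(nib.Nifti1Image(field.directions.astype(np.float32), aff),
             str(prefix) + ".dirs.nii.gz")
    nib.save(nib.Nifti1Image(field.fa.astype(np.float32), aff),
             str(prefix) + ".fa.nii.gz")


def read_direction_field(prefix) -> DirectionField:
    dirs_img = nib.load(str(prefix) + ".dirs.nii.gz")
    fa_img = nib.load(str(prefix) + ".fa.nii.gz")
    voxel_size = tuple(float(v) for v in dirs_img.header.get_zooms()[:3])
    return DirectionField(directions=np.asarray(dirs_img.dataobj, float),
                          fa=np.asarray(fa_img.dataobj, float),
                          voxel_size=voxel_size)


def write_label_volume(path, labels: np.ndarray, voxel_size=(1, 1, 1)) -> None:
    nib.save(nib.Nifti1Image(labels.astype(np.int32), _affine(voxel_size)),
             str(path))


def read_parcellation(path, node_names) -> Parcellation:
    img = nib.load(str(path))
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    return Parcellation(label_volume=np.asarray(img.dataobj).astype(np.int32),
                        node_names=list(node_names), voxel_size=voxel_size)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
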