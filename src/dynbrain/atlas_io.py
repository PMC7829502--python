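"""Interchange I/O: node->network atlas, subject cohorts, and motion QC.

The atlas maps each region-of-interest (node) of a brain parcellation to
exactly one functional network (a partition of ``1..n_nodes``).  The
package ships the Power 264-node / 14-network table as its default atlas.
Subject data travel as plain-text TSV: one ``nodes x volumes`` time-series
file per subject plus a cohort manifest carrying demographics, cognitive
scores and file paths.

Motion quality control follows the framewise-displacement (FD) convention
of Power et al.: FD at a volume transition is the sum of the absolute
differences of the six rigid-body parameters, with the three rotations
(radians) converted to arc length on a 50 mm sphere.  A subject is
excluded when mean FD exceeds 0.2 mm, any translation exceeds 2 mm, or
any rotation exceeds 2 degrees (all strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dynbrain")

#: Radius (mm) of the sphere used to convert rotations to displacements.
FD_ROTATION_RADIUS_MM = 50.0

#: Exclusion thresholds: mean FD (mm), max |translation| (mm), max |rotation| (deg).
FD_MEAN_THRESHOLD_MM = 0.2
MAX_TRANSLATION_MM = 2.0
MAX_ROTATION_DEG = 2.0

GROUPS = ("HC", "noHE", "MHE", "unlabeled")


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Network:
    """One functional network: name, short label and 1-based member nodes."""

    name: str
    abbreviation: str
    nodes: tuple[int, ...]


@dataclass(frozen=True)
class Atlas:
    """A partition of nodes ``1..n_nodes`` into named functional networks."""

    n_nodes: int
    networks: tuple[Network, ...]

    @property
    def node_to_network(self) -> dict[int, str]:
        """Total map from 1-based node index to network name."""
        out: dict[int, str] = {}
        for net in self.networks:
            for node in net.nodes:
                out[node] = net.name
        return out

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(net.abbreviation for net in self.networks)

    def members(self, abbreviation: str) -> tuple[int, ...]:
        for net in self.networks:
            if net.abbreviation == abbreviation:
                return net.nodes
        raise KeyError(abbreviation)

    def validate(self) -> None:
        """Check the partition invariant: no overlaps, no gaps in 1..n_nodes."""
        seen: dict[int, str] = {}
        for net in self.networks:
            for node in net.nodes:
                if node in seen:
                    raise ValueError(
                        f"node {node} assigned to both {seen[node]!r} and {net.name!r}"
                    )
                seen[node] = net.name
        missing = sorted(set(range(1, self.n_nodes + 1)) - set(seen))
        if missing:
            raise ValueError(f"atlas has unassigned nodes: {missing[:10]}")


def expand_member_nodes(text: str) -> tuple[int, ...]:
    """Expand ``"74-83,86-131,137,139"`` into a strictly increasing tuple."""
    nodes: list[int] = []
    for token in str(text).split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token:
            lo, hi = token.split("-")
            lo_i, hi_i = int(lo), int(hi)
            if hi_i < lo_i:
                raise ValueError(f"decreasing range {token!r}")
            nodes.extend(range(lo_i, hi_i + 1))
        else:
            nodes.append(int(token))
    if any(b <= a for a, b in zip(nodes, nodes[1:])):
        raise ValueError(f"member nodes not strictly increasing: {text!r}")
    return tuple(nodes)


def compress_member_nodes(nodes: Sequence[int]) -> str:
    """Inverse of :func:`expand_member_nodes` (consecutive runs as ranges)."""
    out: list[str] = []
    run: list[int] = []
    for n in nodes:
        if run and n == run[-1] + 1:
            run.append(n)
        else:
            if run:
                out.append(str(run[0]) if len(run) == 1 else f"{run[0]}-{run[-1]}")
            run = [n]
    if run:
        out.append(str(run[0]) if len(run) == 1 else f"{run[0]}-{run[-1]}")
    return ",".join(out)


def load_atlas(path: str | Path) -> Atlas:
    """Read an atlas TSV (network_index, network_name, abbreviation, member_nodes)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"network_index", "network_name", "abbreviation", "member_nodes"}
    if not required.issubset(table.columns):
        raise ValueError(f"atlas file missing columns {sorted(required - set(table.columns))}")
    table = table.sort_values("network_index", key=lambda s: s.astype(int))
    networks = tuple(
        Network(row.network_name, row.abbreviation, expand_member_nodes(row.member_nodes))
        for row in table.itertuples()
    )
    n_nodes = max(max(net.nodes) for net in networks)
    atlas = Atlas(n_nodes=n_nodes, networks=networks)
    atlas.validate()
    return atlas


def write_atlas(atlas: Atlas, path: str | Path) -> None:
    rows = [
        {
            "network_index": i + 1,
            "network_name": net.name,
            "abbreviation": net.abbreviation,
            "member_nodes": compress_member_nodes(net.nodes),
        }
        for i, net in enumerate(atlas.networks)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_atlas() -> Atlas:
    """The packaged Power 264-node / 14-network atlas."""
    with resources.as_file(
        resources.files("dynbrain.data") / "power264_networks.tsv"
    ) as p:
        return load_atlas(p)


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "nct_a",
    "dst",
    "blood_ammonia",
    "series_file",
    "motion_file",
)


@dataclass
class SubjectRecord:
    """One subject's ROI time series plus demographics and cognitive scores.

    ``timeseries`` is ``nodes x volumes`` (BOLD-like, arbitrary units);
    ``motion`` is ``volumes x 6`` (translations mm, rotations radians) or
    ``None`` when no motion file is available.
    """

    subject_id: str
    group: str
    timeseries: np.ndarray
    age: float
    sex: str
    education: float
    nct_a: float
    dst: float
    blood_ammonia: float | None = None
    motion: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.timeseries.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.timeseries.shape[1]


def load_subjects(
    manifest: str | Path,
    series_dir: str | Path | None = None,
    atlas: Atlas | None = None,
) -> list[SubjectRecord]:
    """Load a cohort from a manifest TSV, in manifest order.

    Relative file paths are resolved against ``series_dir`` (defaults to the
    manifest's directory).  Series files are header-less ``nodes x volumes``
    TSV; a row-count mismatch against ``atlas`` is a per-subject hard error.
    """
    manifest = Path(manifest)
    base = Path(series_dir) if series_dir is not None else manifest.parent
    table = pd.read_csv(manifest, sep="\t", dtype={"subject_id": str, "group": str, "sex": str})
    records: list[SubjectRecord] = []
    for row in table.itertuples():
        series = np.loadtxt(base / row.series_file, delimiter="\t", ndmin=2)
        if atlas is not None and series.shape[0] != atlas.n_nodes:
            raise ValueError(
                f"subject {row.subject_id}: series has {series.shape[0]} rows, "
                f"atlas expects {atlas.n_nodes}"
            )
        if not np.all(np.isfinite(series)):
            raise ValueError(f"subject {row.subject_id}: non-finite values in series")
        motion = None
        motion_file = getattr(row, "motion_file", "")
        if isinstance(motion_file, str) and motion_file:
            motion = np.loadtxt(base / motion_file, ndmin=2)
        else:
            logger.info("subject %s: no motion data", row.subject_id)
        ammonia = getattr(row, "blood_ammonia", np.nan)
        records.append(
            SubjectRecord(
                subject_id=row.subject_id,
                group=row.group,
                timeseries=series,
                age=float(row.age),
                sex=str(row.sex),
                education=float(row.education),
                nct_a=float(row.nct_a),
                dst=float(row.dst),
                blood_ammonia=None if pd.isna(ammonia) else float(ammonia),
                motion=motion,
            )
        )
    return records


def write_cohort(records: Iterable[SubjectRecord], outdir: str | Path) -> Path:
    """Write subjects in the manifest + TSV layout; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        series_file = f"{rec.subject_id}_series.tsv"
        np.savetxt(outdir / series_file, rec.timeseries, delimiter="\t", fmt="%.6f")
        motion_file = ""
        if rec.motion is not None:
            motion_file = f"{rec.subject_id}_motion.txt"
            np.savetxt(outdir / motion_file, rec.motion, fmt="%.8f")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "age": rec.age,
                "sex": rec.sex,
                "education": rec.education,
                "nct_a": rec.nct_a,
                "dst": rec.dst,
                "blood_ammonia": "" if rec.blood_ammonia is None else rec.blood_ammonia,
                "series_file": series_file,
                "motion_file": motion_file,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Motion QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcReport:
    subject_id: str
    mean_fd: float | None
    max_translation: float | None
    max_rotation: float | None  # degrees
    excluded: bool
    reason: str


def framewise_displacement(
    motion: np.ndarray, rotations_first: bool = False
) -> np.ndarray:
    """Per-transition FD (mm) from a ``volumes x 6`` rigid-body parameter matrix.

    Power convention: sum of absolute framewise differences of the six
    parameters, rotations (radians) scaled by a 50 mm sphere radius.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise ValueError("motion must be volumes x 6 with at least 2 volumes")
    if rotations_first:
        motion = motion[:, [3, 4, 5, 0, 1, 2]]
    diffs = np.abs(np.diff(motion, axis=0))
    return diffs[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * diffs[:, 3:].sum(axis=1)


def qc_motion(subject: SubjectRecord, rotations_first: bool = False) -> QcReport:
    """QC report for one subject; strict-inequality thresholds, Power FD."""
    if subject.motion is None:
        logger.warning("subject %s: QC skipped, no motion data", subject.subject_id)
        return QcReport(subject.subject_id, None, None, None, False, "no motion data")
    motion = np.asarray(subject.motion, dtype=float)
    if rotations_first:
        motion = motion[:, [3, 4, 5, 0, 1, 2]]
    fd = framewise_displacement(motion)
    mean_fd = float(fd.mean())
    max_trans = float(np.abs(motion[:, :3]).max())
    max_rot = float(np.degrees(np.abs(motion[:, 3:]).max()))
    reasons = []
    if mean_fd > FD_MEAN_THRESHOLD_MM:
        reasons.append(f"mean FD {mean_fd:.3f} mm > {FD_MEAN_THRESHOLD_MM} mm")
    if max_trans > MAX_TRANSLATION_MM:
        reasons.append(f"max translation {max_trans:.3f} mm > {MAX_TRANSLATION_MM} mm")
    if max_rot > MAX_ROTATION_DEG:
        reasons.append(f"max rotation {max_rot:.3f} deg > {MAX_ROTATION_DEG} deg")
    return QcReport(
        subject_id=subject.subject_id,
        mean_fd=mean_fd,
        max_translation=max_trans,
        max_rotation=max_rot,
        excluded=bool(reasons),
        reason="; ".join(reasons) if reasons else "ok",
    )


def qc_table(reports: Iterable[QcReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])
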