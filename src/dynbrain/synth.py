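"""Synthetic BOLD-like cohorts with planted dynamic community structure.

Every downstream stage is validated against cohorts generated here, because
no patient fMRI is available at desk scale.  The generative model is
deliberately minimal:

* Time is divided into equal *epochs*; within an epoch every node belongs to
  one module (initially its atlas network).  Each module has one latent
  standard-normal driver per volume, plus a global driver shared by all
  nodes.  A node's signal is ``c*global + a*driver[module] + b*noise`` with
  coefficients solved so that the expected Pearson correlation is
  ``within_module_corr`` inside a module and ``between_module_corr`` across
  modules (``r = a^2/(a^2 + b^2)`` mixture algebra on unit-variance parts,
  ``b = noise_sd``).
* At each epoch boundary nodes may switch module: a *disjoint* event moves
  exactly one node alone; a *cohesive* event moves two nodes of one source
  module to a common destination.  Moves persist until a later event.
* An MHE-like group effect adds extra disjoint-switch probability on
  designated nodes concentrated in "higher-cognitive" (DMN/FPN/VAN-like)
  networks, and cognitive scores are linearly linked to the planted
  disjointness (DST with negative slope, NCT-A with positive slope) plus
  age/education terms and Gaussian noise.

Epoch boundaries are aligned to window strides (one analysis window per
epoch in the default design) so planted changes are recoverable exactly
when modules are recovered.  Ground-truth change counts are derived from
the planted per-epoch label sequence with the same source-and-destination
rule the metrics stage uses, so counts are consistent with the schedule by
construction.  The model makes no attempt at hemodynamic responses,
scanner noise spectra or head-motion artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .atlas_io import Atlas, Network, SubjectRecord

MODES = ("disjoint", "cohesive")


@dataclass(frozen=True)
class SwitchEvent:
    """One planted community switch at an epoch boundary (1-based boundary b
    sits between epoch b and epoch b+1)."""

    boundary: int
    nodes: tuple[int, ...]       # 1-based node indices
    mode: str                    # "disjoint" (1 node) or "cohesive" (>= 2 nodes)
    destination_module: int      # 1-based module id

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "disjoint" and len(self.nodes) != 1:
            raise ValueError("a disjoint event moves exactly 1 node")
        if self.mode == "cohesive" and len(self.nodes) < 2:
            raise ValueError("a cohesive event moves at least 2 nodes")


def synthetic_atlas(n_nodes: int = 40, n_networks: int = 5) -> Atlas:
    """Equal-sized synthetic atlas; the last three networks play the role of
    the higher-cognitive DMN/FPN/VAN systems."""
    if n_nodes % n_networks:
        raise ValueError("n_nodes must be divisible by n_networks")
    size = n_nodes // n_networks
    names = ["Somatomotor-like", "Visual-like", "DMN-like", "FPN-like", "VAN-like",
             "Net6", "Net7", "Net8"][:n_networks]
    abbrs = ["SM", "VIS", "DMN", "FPN", "VAN", "N6", "N7", "N8"][:n_networks]
    networks = tuple(
        Network(names[k], abbrs[k], tuple(range(k * size + 1, (k + 1) * size + 1)))
        for k in range(n_networks)
    )
    atlas = Atlas(n_nodes=n_nodes, networks=networks)
    atlas.validate()
    return atlas


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of the generative model (one subject)."""

    atlas: Atlas
    n_volumes: int = 150
    tr: float = 2.5
    epoch_length: int = 30
    within_module_corr: float = 0.6
    between_module_corr: float = 0.1
    noise_sd: float = 1.0
    switch_schedule: tuple[SwitchEvent, ...] = ()
    base_disjoint_prob: float = 0.05   # per node per boundary
    base_cohesive_prob: float = 0.15   # per module per boundary (one pair event)

    def __post_init__(self) -> None:
        if not (0 <= self.between_module_corr < self.within_module_corr < 1):
            raise ValueError("need 0 <= between_module_corr < within_module_corr < 1")
        if self.epoch_length < 3:
            raise ValueError("epochs must span at least 3 volumes")
        if self.n_volumes % self.epoch_length:
            raise ValueError("n_volumes must be a whole number of epochs")
        for ev in self.switch_schedule:
            if ev.boundary < 1 or ev.boundary >= self.n_epochs:
                raise ValueError(f"boundary {ev.boundary} outside 1..{self.n_epochs - 1}")
            for node in ev.nodes:
                if not 1 <= node <= self.atlas.n_nodes:
                    raise ValueError(f"switching node {node} outside atlas")
            if not 1 <= ev.destination_module <= self.n_modules:
                raise ValueError(f"destination module {ev.destination_module} undefined")

    @property
    def n_nodes(self) -> int:
        return self.atlas.n_nodes

    @property
    def n_epochs(self) -> int:
        return self.n_volumes // self.epoch_length

    @property
    def n_modules(self) -> int:
        return len(self.atlas.networks)


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-epoch labels and the change counts they imply."""

    epoch_labels: np.ndarray       # (n_epochs, n_nodes), 1-based module ids
    disjoint_count: np.ndarray     # (n_nodes,)
    cohesive_count: np.ndarray     # (n_nodes,)
    effect_nodes: tuple[int, ...] = ()   # 1-based nodes with elevated disjointness

    @property
    def change_count(self) -> np.ndarray:
        return self.disjoint_count + self.cohesive_count


def _planted_counts(epoch_labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classify planted label changes with the source+destination rule."""
    n_epochs, n_nodes = epoch_labels.shape
    disjoint = np.zeros(n_nodes)
    cohesive = np.zeros(n_nodes)
    for b in range(n_epochs - 1):
        movers = np.flatnonzero(epoch_labels[b] != epoch_labels[b + 1])
        groups: dict[tuple[int, int], list[int]] = {}
        for i in movers:
            key = (int(epoch_labels[b, i]), int(epoch_labels[b + 1, i]))
            groups.setdefault(key, []).append(int(i))
        for nodes in groups.values():
            target = cohesive if len(nodes) >= 2 else disjoint
            for i in nodes:
                target[i] += 1
    return disjoint, cohesive


def _epoch_labels(design: PlantedDesign) -> np.ndarray:
    labels = np.zeros((design.n_epochs, design.n_nodes), dtype=np.int64)
    for m, net in enumerate(design.atlas.networks, start=1):
        labels[0, np.asarray(net.nodes) - 1] = m
    by_boundary: dict[int, list[SwitchEvent]] = {}
    for ev in design.switch_schedule:
        by_boundary.setdefault(ev.boundary, []).append(ev)
    for e in range(1, design.n_epochs):
        labels[e] = labels[e - 1]
        for ev in by_boundary.get(e, []):
            labels[e, np.asarray(ev.nodes) - 1] = ev.destination_module
    return labels


def generate_subject(
    design: PlantedDesign,
    seed: int | np.random.SeedSequence,
    subject_id: str = "S000",
    group: str = "unlabeled",
    **covariates,
) -> tuple[SubjectRecord, GroundTruth]:
    """One subject's BOLD-like series following the design's switch schedule.

    Deterministic given the seed.  Demographic/score fields default to
    neutral values and may be overridden via keyword arguments.
    """
    rng = np.random.default_rng(seed)
    labels = _epoch_labels(design)
    rw, rb, b = design.within_module_corr, design.between_module_corr, design.noise_sd
    # unit-free mixture: total variance v chosen so b is the noise sd
    v = b * b / (1.0 - rw)
    c = np.sqrt(rb * v)
    a = np.sqrt((rw - rb) * v)
    series = np.empty((design.n_nodes, design.n_volumes))
    L = design.epoch_length
    for e in range(design.n_epochs):
        sl = slice(e * L, (e + 1) * L)
        g = rng.standard_normal(L)
        drivers = rng.standard_normal((design.n_modules + 1, L))
        eps = rng.standard_normal((design.n_nodes, L))
        series[:, sl] = c * g + a * drivers[labels[e]] + b * eps
    disjoint, cohesive = _planted_counts(labels)
    motion = _synthetic_motion(rng, design.n_volumes)
    record = SubjectRecord(
        subject_id=subject_id,
        group=group,
        timeseries=series,
        age=float(covariates.get("age", 50.0)),
        sex=str(covariates.get("sex", "M")),
        education=float(covariates.get("education", 12.0)),
        nct_a=float(covariates.get("nct_a", np.nan)),
        dst=float(covariates.get("dst", np.nan)),
        blood_ammonia=covariates.get("blood_ammonia"),
        motion=motion,
    )
    truth = GroundTruth(
        epoch_labels=labels,
        disjoint_count=disjoint,
        cohesive_count=cohesive,
        effect_nodes=tuple(covariates.get("effect_nodes", ())),
    )
    return record, truth


def _synthetic_motion(rng: np.random.Generator, n_volumes: int) -> np.ndarray:
    """Slow random-walk rigid-body parameters with sub-threshold FD."""
    trans = np.cumsum(rng.normal(0.0, 0.008, size=(n_volumes, 3)), axis=0)
    rots = np.cumsum(rng.normal(0.0, 0.00012, size=(n_volumes, 3)), axis=0)
    return np.hstack([trans, rots])


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupEffects:
    """Group-specific perturbations planted into the cohort.

    ``extra_disjoint_prob`` is added to the per-boundary disjoint-switch
    probability of ``effect_nodes`` for subjects in ``target_groups``.
    Score links: DST decreases and NCT-A increases with the subject's mean
    planted disjointness over the designated higher-cognitive networks.
    """

    extra_disjoint_prob: float = 0.3
    effect_nodes: tuple[int, ...] | None = None   # default: 10 nodes in DMN/FPN/VAN-like
    target_groups: tuple[str, ...] = ("MHE",)
    designated_networks: tuple[str, ...] = ("DMN", "FPN", "VAN")
    dst_slope: float = -110.0
    nct_slope: float = 280.0
    dst_noise_sd: float = 5.0
    nct_noise_sd: float = 6.0


def default_design() -> PlantedDesign:
    """The default 40-node / 5-network study design (5 epochs of 30 volumes)."""
    return PlantedDesign(atlas=synthetic_atlas(40, 5))


def default_effect_nodes(atlas: Atlas, effects: GroupEffects) -> tuple[int, ...]:
    if effects.effect_nodes is not None:
        return effects.effect_nodes
    nodes: list[int] = []
    quota = {"DMN": 3, "FPN": 3, "VAN": 4}
    for abbr in effects.designated_networks:
        members = atlas.members(abbr)
        nodes.extend(members[: quota.get(abbr, 3)])
    return tuple(nodes[:10])


def _sample_schedule(
    design: PlantedDesign,
    rng: np.random.Generator,
    extra_nodes: tuple[int, ...],
    extra_prob: float,
) -> tuple[SwitchEvent, ...]:
    """Random schedule: cohesive pair events per module, base disjoint moves,
    and extra disjoint moves on the effect nodes.  Destinations are sampled
    so no two events at one boundary share a (source, destination) pair,
    keeping planted event kinds unambiguous."""
    events: list[SwitchEvent] = []
    labels = _epoch_labels(replace(design, switch_schedule=()))
    current = labels[0].copy()
    n_modules = design.n_modules
    extra_set = set(extra_nodes)
    for b in range(1, design.n_epochs):
        used_pairs: set[tuple[int, int]] = set()
        moving: set[int] = set()
        boundary_events: list[SwitchEvent] = []
        # cohesive pair events, one candidate per source module
        for m in range(1, n_modules + 1):
            members = np.flatnonzero(current == m) + 1
            if len(members) >= 3 and rng.random() < design.base_cohesive_prob:
                pair = tuple(int(x) for x in rng.choice(members, size=2, replace=False))
                dests = [d for d in range(1, n_modules + 1) if d != m and (m, d) not in used_pairs]
                if not dests:
                    continue
                dest = int(rng.choice(dests))
                used_pairs.add((m, dest))
                moving.update(pair)
                boundary_events.append(SwitchEvent(b, pair, "cohesive", dest))
        # disjoint moves (base everywhere, extra on effect nodes)
        for node in range(1, design.n_nodes + 1):
            if node in moving:
                continue
            p = design.base_disjoint_prob + (extra_prob if node in extra_set else 0.0)
            if rng.random() < p:
                src = int(current[node - 1])
                dests = [d for d in range(1, n_modules + 1) if d != src and (src, d) not in used_pairs]
                if not dests:
                    continue
                dest = int(rng.choice(dests))
                used_pairs.add((src, dest))
                moving.add(node)
                boundary_events.append(SwitchEvent(b, (node,), "disjoint", dest))
        for ev in boundary_events:
            current[np.asarray(ev.nodes) - 1] = ev.destination_module
        events.extend(boundary_events)
    return tuple(events)


def generate_cohort(
    n_per_group: Mapping[str, int],
    base_design: PlantedDesign | None = None,
    group_effects: GroupEffects | None = None,
    seed: int = 0,
) -> list[tuple[SubjectRecord, GroundTruth]]:
    """A full cohort (default group sizes HC 41 / noHE 32 / MHE 30).

    Covariates: age ~ N(50, 7.5) yr, education ~ N(12.5, 3) yr, sex ~ 65% M.
    DST and NCT-A follow linear models in age, education and the subject's
    planted mean disjointness over the designated networks, with Gaussian
    noise; blood ammonia (patients only) increases with the same quantity.
    Deterministic given the seed (per-subject seeds fan out of a
    SeedSequence, so group order cannot change results).
    """
    design = base_design if base_design is not None else default_design()
    effects = group_effects if group_effects is not None else GroupEffects()
    if any(n <= 0 for n in n_per_group.values()) or not n_per_group:
        raise ValueError("every group must have at least one subject")
    effect_nodes = default_effect_nodes(design.atlas, effects)
    designated_idx = np.concatenate(
        [np.asarray(design.atlas.members(a)) - 1 for a in effects.designated_networks]
    )
    cohort: list[tuple[SubjectRecord, GroundTruth]] = []
    sidx = 0
    for grp, count in n_per_group.items():
        for j in range(count):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(sidx,)))
            extra = effects.extra_disjoint_prob if grp in effects.target_groups else 0.0
            schedule = _sample_schedule(design, rng, effect_nodes, extra)
            subj_design = replace(design, switch_schedule=schedule)
            age = float(np.clip(rng.normal(50.0, 7.5), 25, 70))
            education = float(np.clip(rng.normal(12.5, 3.0), 6, 19))
            sex = "M" if rng.random() < 0.65 else "F"
            rec, truth = generate_subject(
                subj_design,
                np.random.SeedSequence(seed, spawn_key=(sidx, 1)),
                subject_id=f"{grp}{j + 1:03d}",
                group=grp,
                age=age,
                sex=sex,
                education=education,
                effect_nodes=effect_nodes,
            )
            d = float(truth.disjoint_count[designated_idx].mean()) / (design.n_epochs - 1)
            dst = (48.0 - 0.15 * (age - 50.0) + 0.8 * (education - 12.5)
                   + effects.dst_slope * d + rng.normal(0.0, effects.dst_noise_sd))
            nct = (28.0 + 0.25 * (age - 50.0) - 0.8 * (education - 12.5)
                   + effects.nct_slope * d + rng.normal(0.0, effects.nct_noise_sd))
            rec.dst = dst
            rec.nct_a = nct
            if grp in ("noHE", "MHE"):
                rec.blood_ammonia = float(max(5.0, 40.0 + 180.0 * d + rng.normal(0.0, 15.0)))
            cohort.append((rec, truth))
            sidx += 1
    return cohort


# ---------------------------------------------------------------------------
# Design (de)serialization
# ---------------------------------------------------------------------------

def design_to_json(design: PlantedDesign, path: str | Path) -> None:
    payload = {
        "n_nodes": design.n_nodes,
        "n_networks": design.n_modules,
        "n_volumes": design.n_volumes,
        "tr": design.tr,
        "epoch_length": design.epoch_length,
        "within_module_corr": design.within_module_corr,
        "between_module_corr": design.between_module_corr,
        "noise_sd": design.noise_sd,
        "base_disjoint_prob": design.base_disjoint_prob,
        "base_cohesive_prob": design.base_cohesive_prob,
        "switch_schedule": [
            {
                "boundary": ev.boundary,
                "nodes": list(ev.nodes),
                "mode": ev.mode,
                "destination_module": ev.destination_module,
            }
            for ev in design.switch_schedule
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def design_from_json(path: str | Path) -> PlantedDesign:
    payload = json.loads(Path(path).read_text())
    atlas = synthetic_atlas(payload["n_nodes"], payload["n_networks"])
    schedule = tuple(
        SwitchEvent(ev["boundary"], tuple(ev["nodes"]), ev["mode"], ev["destination_module"])
        for ev in payload.get("switch_schedule", [])
    )
    return PlantedDesign(
        atlas=atlas,
        n_volumes=payload["n_volumes"],
        tr=payload["tr"],
        epoch_length=payload["epoch_length"],
        within_module_corr=payload["within_module_corr"],
        between_module_corr=payload["between_module_corr"],
        noise_sd=payload["noise_sd"],
        switch_schedule=schedule,
        base_disjoint_prob=payload.get("base_disjoint_prob", 0.05),
        base_cohesive_prob=payload.get("base_cohesive_prob", 0.15),
    )
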