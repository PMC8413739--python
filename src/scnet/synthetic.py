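"""Synthetic cohorts with block-structured regional covariance.

The study data this pipeline targets (per-subject amygdala-nucleus and
hippocampal-subfield volumes for two clinical groups) are not publicly
archived, so every pipeline stage is exercised on cohorts drawn from an
explicit generative model:

* each region's percent-of-TIV volume is a region mean plus linear age and
  sex effects plus correlated Gaussian noise;
* the noise is drawn from an explicit target correlation matrix built from
  a block layout: ``within_block_r`` inside a block, ``between_block_r``
  across blocks.  The default layout is a single whole-system block —
  structural covariance networks of these tightly coupled medial-temporal
  regions are near-uniformly strong, so the default cohort has one global
  correlation level (0.7) per group.  An anatomical 8-block layout
  (amygdala / hippocampal head / body / tail-fissure, per hemisphere) is
  available for structured simulations and anchors the hub experiment;
* the matrix is checked for positive semi-definiteness at construction and
  sampling uses its symmetric square root;
* percent volumes are converted to absolute mm^3 through a subject-specific
  TIV, inverting the normalization the pipeline applies on ingestion.

Group differences are planted by lowering one group's within-block
correlation (with the whole-system block this lowers that group's overall
covariance level and hence its mean clustering coefficient, the direction
reported for patients) or by rerouting one anatomical block's connectivity
through a designated hub region (raises that node's betweenness
centrality in the shifted group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import (
    CANONICAL_TO_FREESURFER,
    CohortTable,
    META_COLUMNS,
    RegionAtlas,
    default_atlas,
    write_cohort_csv,
)

logger = logging.getLogger("scnet.synthetic")

__all__ = [
    "SyntheticConfig",
    "HubShift",
    "SyntheticConfigError",
    "default_block_assignment",
    "anatomical_block_assignment",
    "default_mean_volumes",
    "group_correlation_matrix",
    "generate_cohort",
    "plant_group_difference",
    "write_fixture_files",
]


class SyntheticConfigError(ValueError):
    """Raised for generative configurations without a valid correlation
    structure (e.g. correlations outside [0, 1) or non-PSD targets)."""


#: Per-hemisphere mean total volume as percent of TIV; the per-region means
#: split these evenly within each structure.  Matches the scale of reported
#: whole-structure totals (~0.12% amygdala, ~0.23% hippocampus per side).
AMYGDALA_TOTAL_PCT = 0.12
HIPPOCAMPUS_TOTAL_PCT = 0.235

#: Target correlations for a fully hub-rerouted block (see ``HubShift``):
#: the block's members decouple from each other and from the rest of the
#: network but stay moderately tied to the hub, which keeps a strong (0.6)
#: outward correlation — so shortest paths within the block and from the
#: block outward run through the hub.  Chosen inside the PSD-feasible
#: region for an 8-member block carved out of a uniform-0.7 background.
_HUB_MEMBER_MEMBER_R = 0.15
_HUB_MEMBER_OUTSIDE_R = 0.05
_HUB_MEMBER_HUB_R = 0.35
_HUB_OUTSIDE_R = 0.60


def default_block_assignment(atlas: RegionAtlas) -> dict[str, int]:
    """One whole-system block: every region in block 0.

    The default cohort therefore has a single global correlation level per
    group (``within_block_r``), the regime the reported group networks'
    near-saturated transitivity and average strength imply.
    """
    return {r.name: 0 for r in atlas.regions}


def anatomical_block_assignment(atlas: RegionAtlas) -> dict[str, int]:
    """Anatomically grouped blocks: per hemisphere, the amygdala
    nuclei, hippocampal head, hippocampal body, and tail/fimbria/fissure
    regions (8 blocks for the default 56-region atlas)."""
    tail_group = {"fimbria", "hippocampal-tail", "hippocampal-fissure"}
    assignment: dict[str, int] = {}
    for region in atlas.regions:
        base = 0 if region.hemisphere == "left" else 4
        stem = region.name.split("_", 1)[1]
        if region.structure == "amygdala":
            block = base + 0
        elif stem in tail_group:
            block = base + 3
        elif stem.endswith("-body"):
            block = base + 2
        else:  # head subfields, parasubiculum, amygdala-transition area
            block = base + 1
        assignment[region.name] = block
    return assignment


def default_mean_volumes(atlas: RegionAtlas) -> dict[str, float]:
    """Per-region mean volumes in percent of TIV (flat within structure)."""
    n_amyg = sum(r.structure == "amygdala" and r.hemisphere == "left"
                 for r in atlas.regions)
    n_hippo = sum(r.structure == "hippocampus" and r.hemisphere == "left"
                  for r in atlas.regions)
    means = {}
    for region in atlas.regions:
        if region.structure == "amygdala":
            means[region.name] = AMYGDALA_TOTAL_PCT / n_amyg
        else:
            means[region.name] = HIPPOCAMPUS_TOTAL_PCT / n_hippo
    return means


@dataclass(frozen=True)
class HubShift:
    """Reroute one anatomical block's connectivity through ``hub_region``
    in ``group``.

    The hub's anatomical block (under :func:`anatomical_block_assignment`)
    is carved out of the group's correlation matrix: its members decouple
    from the rest of the network and from each other but stay tied to the
    hub, which keeps its baseline connectivity outward.  ``magnitude`` in
    [0, 1] interpolates linearly between the base structure (0: no change)
    and the full rerouting (1).
    """

    group: str
    hub_region: str = "right_ca1-head"
    magnitude: float = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative settings for a two-group synthetic cohort.

    ``within_block_r`` may be a single float (both groups share it) or a
    per-group pair ordered like ``group_names``.
    """

    n_per_group: tuple[int, int] = (35, 34)
    group_names: tuple[str, str] = ("patients", "controls")
    atlas: RegionAtlas = field(default_factory=default_atlas)
    block_assignment: dict[str, int] | None = None
    within_block_r: float | tuple[float, float] = 0.7
    between_block_r: float = 0.3
    age_range: tuple[float, float] = (18.0, 35.0)
    sex_balance: float = 0.5  # fraction coded 1 (male)
    beta_age: float = -5e-5  # %TIV per year, per region
    beta_sex: float = 5e-4  # %TIV shift for sex code 1
    noise_sd: float = 0.002  # %TIV
    mean_volumes: dict[str, float] | None = None
    tiv_mean: float = 1.45e6  # mm^3
    tiv_sd: float = 1.3e5  # mm^3
    hub_shift: HubShift | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        multi_block = len(set(self.blocks().values())) > 1
        for g, r in zip(self.group_names, self.within_block_r_pair()):
            if not 0 <= r < 1:
                raise SyntheticConfigError(
                    f"within_block_r for group {g!r} must lie in [0, 1), "
                    f"got {r}"
                )
            if multi_block and r < self.between_block_r:
                raise SyntheticConfigError(
                    f"within_block_r ({r}) must be >= between_block_r "
                    f"({self.between_block_r}) for group {g!r}"
                )
        if not 0 <= self.between_block_r < 1:
            raise SyntheticConfigError(
                f"between_block_r must lie in [0, 1), got "
                f"{self.between_block_r}"
            )
        if self.hub_shift is not None:
            if self.hub_shift.group not in self.group_names:
                raise SyntheticConfigError(
                    f"hub_shift group {self.hub_shift.group!r} not in "
                    f"{self.group_names}"
                )
            if self.hub_shift.hub_region not in self.atlas.names:
                raise SyntheticConfigError(
                    f"hub_shift region {self.hub_shift.hub_region!r} not "
                    "in atlas"
                )
            if not 0 <= self.hub_shift.magnitude <= 1:
                raise SyntheticConfigError("hub_shift magnitude must lie "
                                           "in [0, 1]")
        if any(n < 1 for n in self.n_per_group):
            raise SyntheticConfigError("n_per_group entries must be >= 1")

    def within_block_r_pair(self) -> tuple[float, float]:
        r = self.within_block_r
        if isinstance(r, (int, float)):
            return (float(r), float(r))
        return (float(r[0]), float(r[1]))

    def blocks(self) -> dict[str, int]:
        return self.block_assignment or default_block_assignment(self.atlas)

    def means(self) -> dict[str, float]:
        return self.mean_volumes or default_mean_volumes(self.atlas)


# ---------------------------------------------------------------------------
# Target correlation matrices
# ---------------------------------------------------------------------------


def group_correlation_matrix(
    config: SyntheticConfig, group: str
) -> np.ndarray:
    """The group's target inter-regional noise correlation matrix.

    Entries are ``within_block_r`` (the group's value) inside a block and
    ``between_block_r`` across blocks; a planted hub shift then carves the
    hub's anatomical block.  Raises if the result is not positive
    semi-definite.
    """
    names = config.atlas.names
    blocks = config.blocks()
    block_idx = np.array([blocks[n] for n in names])
    gi = config.group_names.index(group)
    r_w = config.within_block_r_pair()[gi]
    r_b = config.between_block_r
    same_block = block_idx[:, None] == block_idx[None, :]
    sigma = np.where(same_block, r_w, r_b)
    np.fill_diagonal(sigma, 1.0)

    shift = config.hub_shift
    if shift is not None and shift.group == group:
        m = shift.magnitude
        hub = config.atlas.index(shift.hub_region)
        anat = anatomical_block_assignment(config.atlas)
        hub_block = anat[shift.hub_region]
        members = np.array(
            [i for i, n in enumerate(names)
             if anat[n] == hub_block and i != hub]
        )
        outside = np.array(
            [i for i in range(len(names))
             if i != hub and i not in set(members)]
        )
        full = sigma.copy()
        full[np.ix_(members, members)] = _HUB_MEMBER_MEMBER_R
        full[np.ix_(members, outside)] = _HUB_MEMBER_OUTSIDE_R
        full[np.ix_(outside, members)] = _HUB_MEMBER_OUTSIDE_R
        full[members, hub] = _HUB_MEMBER_HUB_R
        full[hub, members] = _HUB_MEMBER_HUB_R
        full[outside, hub] = _HUB_OUTSIDE_R
        full[hub, outside] = _HUB_OUTSIDE_R
        np.fill_diagonal(full, 1.0)
        sigma = (1 - m) * sigma + m * full

    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals.min() < -1e-8:
        raise SyntheticConfigError(
            f"group {group!r}: implied correlation matrix is not positive "
            f"semi-definite (min eigenvalue {eigvals.min():.3g})"
        )
    return sigma


def _sigma_sqrt(sigma: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix (tiny negatives clipped)."""
    eigvals, eigvecs = np.linalg.eigh(sigma)
    return eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw a two-group cohort of absolute volumes (mm^3) plus TIV.

    Deterministic for a fixed ``config.seed``.  Subjects whose draw produces
    a negative volume are redrawn (new latents, same covariates) with a
    logged count; under default settings this is a > 5-sigma event.
    """
    rng = np.random.default_rng(config.seed)
    atlas = config.atlas
    names = list(atlas.names)
    means = np.array([config.means()[n] for n in names])

    rows: list[dict[str, object]] = []
    n_resampled = 0
    counter = 0
    for group, n_subjects in zip(config.group_names, config.n_per_group):
        root = _sigma_sqrt(group_correlation_matrix(config, group))
        for _ in range(n_subjects):
            counter += 1
            age = rng.uniform(*config.age_range)
            sex = int(rng.random() < config.sex_balance)
            tiv = rng.normal(config.tiv_mean, config.tiv_sd)
            while abs(tiv - config.tiv_mean) > 3 * config.tiv_sd:
                tiv = rng.normal(config.tiv_mean, config.tiv_sd)
            for attempt in range(100):
                noise = root @ rng.normal(size=len(names))
                pct = (means + config.beta_age * age
                       + config.beta_sex * sex + config.noise_sd * noise)
                if (pct > 0).all():
                    break
                n_resampled += 1
            else:
                raise SyntheticConfigError(
                    "could not draw positive volumes in 100 attempts; "
                    "check mean_volumes vs noise_sd"
                )
            row: dict[str, object] = {
                "subject_id": f"sub-{counter:03d}",
                "group": group,
                "age": age,
                "sex": sex,
                "tiv": tiv,
            }
            row.update(dict(zip(names, pct * tiv / 100.0)))
            rows.append(row)
    if n_resampled:
        logger.warning("resampled %d subject draws with negative volumes",
                       n_resampled)
    df = pd.DataFrame(rows, columns=list(META_COLUMNS) + names)
    return CohortTable(atlas=atlas, data=df, normalized=False)


def plant_group_difference(
    config: SyntheticConfig,
    effect: str,
    magnitude: float,
) -> SyntheticConfig:
    """Return a config with a planted group difference.

    ``clustering_shift`` lowers the first group's within-block correlation
    by ``magnitude`` (lower clustering in that group); ``hub_shift``
    reroutes the designated hub's block through the hub in the first group
    (higher hub betweenness there), with ``magnitude`` in [0, 1] scaling
    the rerouting.  ``magnitude = 0`` returns an equivalent-groups config.
    """
    if effect == "clustering_shift":
        base = config.within_block_r_pair()
        shifted = base[0] - magnitude
        if not 0 <= shifted < 1:
            raise SyntheticConfigError(
                f"clustering_shift magnitude {magnitude} puts "
                f"within_block_r at {shifted}, outside [0, 1)"
            )
        return replace(config, within_block_r=(shifted, base[1]))
    if effect == "hub_shift":
        return replace(
            config,
            hub_shift=HubShift(group=config.group_names[0],
                               magnitude=magnitude),
        )
    raise SyntheticConfigError(
        f"unknown effect {effect!r}; expected 'clustering_shift' or "
        "'hub_shift'"
    )


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------


def write_fixture_files(cohort: CohortTable, out_dir) -> dict[str, object]:
    """Write a cohort CSV plus per-subject FreeSurfer-dialect subfield files.

    Emits, per subject, four two-column (label, mm^3) text files — left and
    right hippocampal subfields, left and right amygdala nuclei — using the
    FreeSurfer labels (including ``Whole_*`` aggregate rows, which readers
    skip), and one ``cohort.csv``.  Returns the written paths.
    """
    from pathlib import Path

    if cohort.normalized:
        raise SyntheticConfigError(
            "fixture files hold absolute mm^3 volumes; pass the "
            "unnormalized cohort"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = write_cohort_csv(cohort, out / "cohort.csv")
    atlas = cohort.atlas
    roles = {
        "lh_hippo": ("left", "hippocampus", "lh.hippoSfVolumes.txt",
                     "Whole_hippocampus"),
        "rh_hippo": ("right", "hippocampus", "rh.hippoSfVolumes.txt",
                     "Whole_hippocampus"),
        "lh_amyg": ("left", "amygdala", "lh.amygNucVolumes.txt",
                    "Whole_amygdala"),
        "rh_amyg": ("right", "amygdala", "rh.amygNucVolumes.txt",
                    "Whole_amygdala"),
    }
    subject_files: dict[str, dict[str, Path]] = {}
    for _, row in cohort.data.iterrows():
        sid = str(row["subject_id"])
        paths: dict[str, Path] = {}
        for role, (hemi, structure, suffix, aggregate) in roles.items():
            region_names = atlas.subset_names(hemisphere=hemi,
                                              structure=structure)
            lines = []
            total = 0.0
            for name in region_names:
                stem = name.split("_", 1)[1]
                label = CANONICAL_TO_FREESURFER[stem]
                value = float(row[name])
                total += value
                lines.append(f"{label} {value:.17g}")
            lines.append(f"{aggregate} {total:.17g}")
            path = out / f"{sid}.{suffix}"
            path.write_text("\n".join(lines) + "\n")
            paths[role] = path
        subject_files[sid] = paths
    return {"cohort_csv": csv_path, "subject_files": subject_files}
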