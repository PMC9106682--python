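"""Ground-truthed synthetic muscle volume generator.

Generates labeled volumes of parallel quasi-cylindrical myofibrils running
along axis 0, interrupted by thin SRT planes at sarcomere boundaries, with
split and merge junction events of configurable single/multi rates. Every
event transition assigns fresh labels, mirroring a manual tracing protocol
in which a new label is created for each branched segment.

Geometry notes
--------------
Each myofibril owns a disjoint square territory of the cross-section and is
drawn as a digitized disk. A split at a sarcomere boundary ends the current
label and starts a fresh axial ("main") child plus k-1 short side-branch
("stub") children carved from the disk; a merge mirrors this in reverse
(stubs appear shortly before the boundary and fuse into a fresh label).
Stub offsets are chosen, and verified against the actual cell boundary
distance map, so that the main child is always strictly the successor whose
mean boundary distance is closest to the seed's - making downstream
tracking deterministic and exactly recoverable. Events whose side branches
cannot be placed are skipped and counted; multi events that can only fit
one side branch are downgraded to single (also counted).

A myofibril's final sarcomere has no downstream boundary inside the field
of view, so only ``n_sarcomeres - 1`` sarcomeres per myofibril are
"observable" for branching; expected statistics refer to those.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage

from .volume_io import LabeledVolume, MaskVolume, VoxelGrid, VolumeError

__all__ = [
    "GeneratorConfig",
    "GroundTruthEvent",
    "SyntheticGroundTruth",
    "generate_muscle_volume",
    "expected_statistics",
]


class GeometryError(VolumeError):
    """Requested geometry cannot be packed into the grid."""


# eight compass directions in (row, col) order
_DIRECTIONS = (
    (0, 1), (0, -1), (1, 0), (-1, 0),
    (0.70710678, 0.70710678), (0.70710678, -0.70710678),
    (-0.70710678, 0.70710678), (-0.70710678, -0.70710678),
)


@dataclass(frozen=True)
class GeneratorConfig:
    grid: VoxelGrid
    n_myofibrils: int
    sarcomere_length: float  # nm
    srt_gap_thickness: float  # nm
    myofibril_radius_mean: float = 100.0  # nm
    myofibril_radius_sd: float = 0.0
    p_single: float = 0.0
    p_multi: float = 0.0
    multi_multiplicity_pmf: dict = field(default_factory=lambda: {3: 1.0})
    p_merge_fraction: float = 0.5
    peripheral_bias: float = 0.0
    cell_margin: float = 60.0  # nm
    n_exiting: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_myofibrils < 1:
            raise VolumeError("n_myofibrils must be >= 1")
        if not (0 <= self.p_single and 0 <= self.p_multi):
            raise VolumeError("event probabilities must be >= 0")
        if self.p_single + self.p_multi > 1.0 + 1e-12:
            raise VolumeError(
                f"p_single + p_multi must be <= 1, got {self.p_single + self.p_multi}"
            )
        if not 0.0 <= self.p_merge_fraction <= 1.0:
            raise VolumeError("p_merge_fraction must lie in [0, 1]")
        if self.peripheral_bias < 0:
            raise VolumeError("peripheral_bias must be >= 0")
        for v in (self.sarcomere_length, self.srt_gap_thickness,
                  self.myofibril_radius_mean, self.cell_margin):
            if v <= 0:
                raise VolumeError("geometric parameters must be > 0")
        pmf = self.multi_multiplicity_pmf
        if any(int(k) < 3 for k in pmf):
            raise VolumeError("multiplicity pmf is over resultant counts k >= 3")
        if abs(sum(pmf.values()) - 1.0) > 1e-9:
            raise VolumeError("multiplicity pmf must sum to 1")
        if not 0 <= self.n_exiting <= self.n_myofibrils:
            raise VolumeError("n_exiting must lie in [0, n_myofibrils]")

    # -- voxel-unit layout helpers -------------------------------------
    @property
    def sarcomere_voxels(self) -> int:
        return max(1, round(self.sarcomere_length / self.grid.voxel_size[0]))

    @property
    def gap_voxels(self) -> int:
        return max(1, round(self.srt_gap_thickness / self.grid.voxel_size[0]))

    @property
    def max_gap(self) -> int:
        """Longitudinal bridging window used by graph construction."""
        return self.gap_voxels + 2

    @property
    def n_sarcomeres(self) -> int:
        n_long = self.grid.shape[0]
        return (n_long + self.gap_voxels) // (self.sarcomere_voxels + self.gap_voxels)

    def boundary_slices(self) -> list[int]:
        """First slice of each internal SRT plane (sarcomere boundaries)."""
        L, gap = self.sarcomere_voxels, self.gap_voxels
        return [t * L + (t - 1) * gap for t in range(1, self.n_sarcomeres)]


@dataclass(frozen=True)
class GroundTruthEvent:
    myofibril: int
    boundary: int  # upstream sarcomere index, 1-based
    z_position: int  # first slice of the downstream segments
    type: str  # split | merge
    classification: str  # single | multi
    parent_labels: tuple[int, ...]
    child_labels: tuple[int, ...]
    branch_count: int


@dataclass
class SyntheticGroundTruth:
    n_myofibrils: int
    n_sarcomeres: int
    segments: list  # (label, myofibril, sarc_from, sarc_to, kind)
    events: list[GroundTruthEvent]
    per_sarcomere_flags: np.ndarray  # (n_myofibrils, n_sarc-1): 0 none, 1 single, 2 multi
    seed_labels: list[int]
    censored_seed_labels: list[int]
    skipped_events: int = 0
    downgraded_events: int = 0

    @property
    def observable_sarcomeres(self) -> int:
        """Sarcomeres with a downstream boundary in the field of view."""
        return (self.n_myofibrils - len(self.censored_seed_labels)) * (
            self.n_sarcomeres - 1
        )


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[-radius: radius + 1, -radius: radius + 1]
    keep = rr**2 + cc**2 <= radius**2
    return rr[keep], cc[keep]


def _pmf_sampler(pmf: dict):
    ks = np.array(sorted(int(k) for k in pmf))
    cdf = np.cumsum([pmf[k] for k in ks])
    def sample(u: float) -> int:
        return int(ks[np.searchsorted(cdf, u, side="right").clip(0, len(ks) - 1)])
    return sample


def generate_muscle_volume(
    config: GeneratorConfig,
) -> tuple[LabeledVolume, MaskVolume, MaskVolume, SyntheticGroundTruth]:
    """Generate (labels, cell mask, srt mask, ground truth) for one config.

    Deterministic: identical config (including seed) gives bit-identical
    outputs.
    """
    n_long, n_row, n_col = config.grid.shape
    dz, dy, dx = config.grid.voxel_size
    L, gap, mg = config.sarcomere_voxels, config.gap_voxels, config.max_gap
    if L < mg + 3:
        raise GeometryError(
            f"sarcomere length of {L} voxels too short for SRT gap {gap}"
        )
    n_sarc = config.n_sarcomeres
    if n_sarc < 2:
        raise GeometryError("volume too short for two sarcomeres")
    stub_len = max(1, min(L // 3, (L - mg - 1) // 2, 6))

    # sarcomere regions along z; the last absorbs leftover slices
    starts = [(t - 1) * (L + gap) for t in range(1, n_sarc + 1)]
    ends = [a + L for a in starts]
    ends[-1] = n_long

    rng = np.random.default_rng(config.seed)
    radii_nm = rng.normal(
        config.myofibril_radius_mean, config.myofibril_radius_sd, config.n_myofibrils
    )
    radii = np.maximum(3, np.round(np.abs(radii_nm) / dy)).astype(int)
    stub_radii = np.maximum(2, radii // 2)
    half = int(radii.max() + stub_radii.max() + 2)
    pitch = 2 * half + 1

    border = 2
    margin = max(1, round(config.cell_margin / dy))
    avail_r = n_row - 2 * (border + margin)
    avail_c = n_col - 2 * (border + margin)
    lat_r, lat_c = avail_r // pitch, avail_c // pitch
    if lat_r * lat_c < config.n_myofibrils:
        raise GeometryError(
            f"grid fits {lat_r * lat_c} myofibrils of radius "
            f"{radii.max()} voxels; {config.n_myofibrils} requested"
        )
    if config.n_exiting > lat_c:
        raise GeometryError("too many exiting myofibrils for one lattice row")

    # exiting myofibrils occupy the first lattice row and drift toward row 0
    positions = [(i, j) for i in range(lat_r) for j in range(lat_c)]
    exiting_pos = positions[: config.n_exiting]
    normal_pos = positions[config.n_exiting:]
    order = exiting_pos + normal_pos  # fibril m -> lattice cell
    centers = [
        (border + margin + half + i * pitch, border + margin + half + j * pitch)
        for i, j in order[: config.n_myofibrils]
    ]
    is_exiting = [m < config.n_exiting for m in range(config.n_myofibrils)]

    cell2d = np.zeros((n_row, n_col), dtype=bool)
    r_lo = 0 if config.n_exiting else border
    cell2d[r_lo: n_row - border, border: n_col - border] = True
    dist2d = ndimage.distance_transform_edt(cell2d, sampling=(dy, dx))

    p_total = config.p_single + config.p_multi
    weights = np.ones(config.n_myofibrils)
    if config.peripheral_bias > 0 and p_total > 0:
        d_c = np.array([dist2d[r, c] for r, c in centers])
        d_ref = d_c.max() if d_c.max() > 0 else 1.0
        weights = np.exp(config.peripheral_bias * (1.0 - d_c / d_ref))
    active = [m for m in range(config.n_myofibrils) if not is_exiting[m]]
    if active and p_total > 0:
        w_mean = weights[active].mean()
        p_fib = np.minimum(0.95, p_total * weights / w_mean)
    else:
        p_fib = np.zeros(config.n_myofibrils)

    U = rng.random((config.n_myofibrils, max(0, n_sarc - 1), 4))
    sample_k = _pmf_sampler(config.multi_multiplicity_pmf)
    margin_nm = 2.0 * min(dy, dx)
    min_lens = 4  # minimum stub/parent footprint intersection, voxels

    next_label = 1
    vol = np.zeros((n_long, n_row, n_col), dtype=np.int32)
    segments, events, seed_labels, censored = [], [], [], []
    flags = np.zeros((config.n_myofibrils, max(0, n_sarc - 1)), dtype=np.int8)
    skipped = downgraded = 0

    for m in range(config.n_myofibrils):
        r, r_stub = int(radii[m]), int(stub_radii[m])
        cy, cx = centers[m]
        d_rr, d_cc = _disk_offsets(r)
        s_rr, s_cc = _disk_offsets(r_stub)
        disk_rows, disk_cols = cy + d_rr, cx + d_cc
        d_base = float(dist2d[disk_rows, disk_cols].mean())

        seed_label = next_label
        next_label += 1
        seed_labels.append(seed_label)

        if is_exiting[m]:
            # drift toward row 0 over the last sarcomeres, end one sarcomere early
            censored.append(seed_label)
            last_t = n_sarc - 1
            drift_t0 = max(1, last_t - 2)
            total_shift = cy - r  # enough to reach row 0
            nd = last_t - drift_t0 + 1
            step = -(-total_shift // nd)
            for t in range(1, last_t + 1):
                shift = min(total_shift, step * (t - drift_t0 + 1)) if t >= drift_t0 else 0
                rows = disk_rows - shift
                keep = rows >= 0
                vol[starts[t - 1]: ends[t - 1], rows[keep], disk_cols[keep]] = seed_label
            segments.append((seed_label, m, 1, last_t, "main"))
            continue

        # --- decide events at each internal boundary --------------------
        main_from = 1
        cur_label = seed_label
        stub_paints = []  # (label, z0, z1, rows, cols)
        for s in range(1, n_sarc):
            u_ev, u_cls, u_typ, u_mult = U[m, s - 1]
            if u_ev >= p_fib[m]:
                continue
            cls = "single" if (p_total > 0 and u_cls < config.p_single / p_total) else "multi"
            typ = "merge" if u_typ < config.p_merge_fraction else "split"
            k = 2 if cls == "single" else sample_k(u_mult)

            # place k-1 stub disks at distance r from the axis
            cands = []
            for idir, (uy, ux) in enumerate(_DIRECTIONS):
                sy, sx = cy + round(r * uy), cx + round(r * ux)
                rows, cols = sy + s_rr, sx + s_cc
                if (rows.min() < cy - half or rows.max() > cy + half
                        or cols.min() < cx - half or cols.max() > cx + half):
                    continue
                inside = dist2d[rows, cols] > 0
                if not inside.all():
                    continue
                lens = ((rows - cy) ** 2 + (cols - cx) ** 2 <= r * r).sum()
                if lens < min_lens:
                    continue
                d_stub = float(dist2d[rows, cols].mean())
                delta = abs(d_stub - d_base)
                if delta < margin_nm:
                    # tracking (in either longitudinal direction) could not
                    # reliably prefer the axial child over this stub
                    continue
                cands.append((delta, idir >= 4, rows, cols))
            # the four diagonals are mutually 90 degrees apart and can host
            # three or four disjoint stubs; prefer them for high multiplicity
            if k - 1 >= 3:
                cands.sort(key=lambda c: (not c[1], -c[0]))
            else:
                cands.sort(key=lambda c: -c[0])
            chosen = []
            taken = np.zeros((n_row, n_col), dtype=bool)
            for delta, _isdiag, rows, cols in cands:
                if len(chosen) == k - 1:
                    break
                pad_r = np.clip(rows[:, None] + np.arange(-1, 2), 0, n_row - 1)
                pad_c = np.clip(cols[:, None] + np.arange(-1, 2), 0, n_col - 1)
                if taken[pad_r[:, :, None], pad_c[:, None, :]].any():
                    continue
                taken[rows, cols] = True
                chosen.append((rows, cols))
            if not chosen:
                skipped += 1
                continue
            k_real = len(chosen) + 1
            cls_real = "single" if k_real == 2 else "multi"
            if cls_real != cls:
                downgraded += 1

            # close out current main segment, allocate fresh labels
            segments.append((cur_label, m, main_from, s, "main"))
            new_main = next_label
            next_label += 1
            stub_labels = list(range(next_label, next_label + len(chosen)))
            next_label += len(chosen)
            z_child = starts[s]  # first slice of sarcomere s+1

            if typ == "split":
                # stubs live in the early part of sarcomere s+1
                z0, z1 = starts[s], starts[s] + stub_len
                parents, children = (cur_label,), tuple([new_main] + stub_labels)
                sarc_of_stub = s + 1
            else:
                # stubs appear in the late part of sarcomere s and merge
                z0, z1 = ends[s - 1] - stub_len, ends[s - 1]
                parents, children = tuple([cur_label] + stub_labels), (new_main,)
                sarc_of_stub = s
            for lab, (rows, cols) in zip(stub_labels, chosen):
                stub_paints.append((lab, z0, z1, rows, cols))
                segments.append((lab, m, sarc_of_stub, sarc_of_stub, "stub"))
            events.append(GroundTruthEvent(
                m, s, z_child, typ, cls_real, parents, children, k_real - 1
            ))
            flags[m, s - 1] = 1 if cls_real == "single" else 2
            cur_label = new_main
            main_from = s + 1

        segments.append((cur_label, m, main_from, n_sarc, "main"))

        # --- paint: full disk per sarcomere region, stubs overwrite -----
        label_of_sarc = {}
        for lab, fib, s0, s1, kind in segments:
            if fib != m or kind != "main":
                continue
            for t in range(s0, s1 + 1):
                label_of_sarc[t] = lab
        for t in range(1, n_sarc + 1):
            vol[starts[t - 1]: ends[t - 1], disk_rows, disk_cols] = label_of_sarc[t]
        for lab, z0, z1, rows, cols in stub_paints:
            vol[z0:z1, rows, cols] = lab

    srt = np.zeros((n_long, n_row, n_col), dtype=np.uint8)
    for t in range(1, n_sarc):
        srt[ends[t - 1]: ends[t - 1] + gap] = cell2d
    cell3d = np.broadcast_to(cell2d, (n_long, n_row, n_col)).astype(np.uint8)

    gt = SyntheticGroundTruth(
        config.n_myofibrils, n_sarc, segments, events, flags,
        seed_labels, censored, skipped, downgraded,
    )
    labels = LabeledVolume(config.grid, vol)
    return (
        labels,
        MaskVolume(config.grid, cell3d, "cell"),
        MaskVolume(config.grid, srt, "SRT"),
        gt,
    )


def expected_statistics(config: GeneratorConfig) -> dict[str, float]:
    """Closed-form expected branching metrics for a generator configuration.

    ``branches_per_10`` counts one branch per single event and ``k - 1`` per
    multi event with ``k`` resultant segments (merges contribute
    identically).
    """
    p_s, p_m = config.p_single, config.p_multi
    e_km1 = sum((int(k) - 1) * p for k, p in config.multi_multiplicity_pmf.items())
    return {
        "pct_branching_sarcomeres": 100.0 * (p_s + p_m),
        "pct_single": 100.0 * p_s,
        "pct_multi": 100.0 * p_m,
        "branches_per_10": 10.0 * (p_s * 1.0 + p_m * e_km1),
    }
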