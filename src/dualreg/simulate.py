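"""Ground-truth cohort simulator for resting-state network analyses.

A simulated subject's data is the product of known network maps and known
per-subject network timecourses, plus voxelwise Gaussian noise and a
voxelwise mean offset:

    Y[v, t] = sum_m S[m, v] * tau_eff[m, v, t] + eps[v, t] + mean[v],
    eps[v, t] ~ Normal(0, noise_std[v]^2)  independently over v, t.

Group differences are injected through three manipulations applied to half
of the cohort (Group B):

* ``network_wide_amplitude`` — one component's timecourse is multiplied by
  a factor (default 1.1, a 10% network-wide amplitude increase) before the
  map-timecourse product.
* ``within_network_amplitude`` — the timecourse used at a subset of one
  network's voxels (a "node", e.g. the PCC within a default-mode analog) is
  multiplied by a factor (default 1.5), creating an amplitude difference
  within the network.
* ``shape_swap`` — a subset of one network's voxels keeps its map weight
  but receives another network's (unnormalized) timecourse, changing both
  networks' shape; because the donor timecourse is not normalized there is
  also a small residual amplitude difference.

Network maps are unions of flat-top spherical blobs (weight 1 inside the
radius) on a small grid; all reported effects are ratios of coefficients,
so the conclusions are independent of grid scale.  Timecourses are
band-limited Gaussian processes (default 0.01–0.1 Hz at TR = 2 s), with
per-subject network amplitudes drawn uniformly to mimic between-subject
amplitude variability.  Every random draw flows from a single seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import BOLDDataset, SpatialMapSet, VolumeGrid, flatten_volumes
from .io import write_4d_image

__all__ = [
    "NetworkBlobSpec",
    "EffectSpec",
    "CohortGroundTruth",
    "default_network_spec",
    "default_cohort_config",
    "make_network_maps",
    "make_timecourses",
    "apply_effects",
    "synthesize_subject",
    "simulate_cohort",
    "build_cohort",
    "blob_mask",
]

EFFECT_KINDS = ("network_wide_amplitude", "within_network_amplitude", "shape_swap")

# Default 8-network layout on a 24x24x16 grid.  Component roles follow the
# classic eight resting-state networks: medial visual, lateral occipital,
# auditory, sensorimotor, default mode, executive control, and right/left
# fronto-parietal.  The DMN has four disjoint nodes (PCC, mPFC, bilateral
# parietal) so a within-network node exists; the ECN has a basal-ganglia/
# thalamus node used by the shape swap.  Blobs are mutually disjoint.
DEFAULT_BLOBS: dict[str, list[tuple[tuple[int, int, int], float]]] = {
    "MVN": [((12, 3, 8), 2.5)],
    "LON": [((4, 5, 8), 2.5), ((20, 5, 8), 2.5)],
    "AUD": [((3, 12, 6), 2.5), ((21, 12, 6), 2.5)],
    "SMN": [((12, 12, 13), 2.5)],
    "DMN": [((12, 8, 9), 2.0), ((12, 21, 5), 2.0), ((5, 10, 11), 2.0), ((19, 10, 11), 2.0)],
    "ECN": [((12, 18, 12), 3.5), ((12, 13, 7), 2.0)],
    "RFPN": [((18, 16, 10), 2.5), ((16, 6, 13), 2.0)],
    "LFPN": [((6, 16, 10), 2.5), ((8, 6, 13), 2.0)],
}


def blob_mask(grid: VolumeGrid, center, radius: float) -> np.ndarray:
    """Flat boolean mask (length N) of voxels within ``radius`` of ``center``."""
    x, y, z = np.meshgrid(*(np.arange(d) for d in grid.dims), indexing="ij")
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return flatten_volumes(d2 <= radius**2)


@dataclass
class NetworkBlobSpec:
    """Blob layout for synthetic network maps.

    ``components`` maps component name -> list of (center, radius) blobs;
    ``weight`` is the in-blob map value (flat-top blobs make coefficient
    ratios directly interpretable).
    """

    grid: VolumeGrid
    components: dict[str, list[tuple[tuple[int, int, int], float]]] = field(
        default_factory=lambda: dict(DEFAULT_BLOBS)
    )
    weight: float = 1.0

    def __post_init__(self):
        if not self.components:
            raise ValueError("need at least one component")
        for name, blobs in self.components.items():
            if not blobs:
                raise ValueError(f"component {name} has no blobs")
            for center, radius in blobs:
                for c, d in zip(center, self.grid.dims):
                    if c - radius < -0.5 or c + radius > d - 0.5:
                        raise ValueError(
                            f"component {name}: blob at {center} (r={radius}) "
                            f"extends outside the {self.grid.dims} grid"
                        )

    @property
    def names(self) -> list[str]:
        return list(self.components)


def default_network_spec(grid: VolumeGrid | None = None) -> NetworkBlobSpec:
    """The default eight-network blob layout on a 24x24x16 grid."""
    if grid is None:
        grid = VolumeGrid(dims=(24, 24, 16), voxel_size=(3.0, 3.0, 3.0))
    return NetworkBlobSpec(grid=grid)


def make_network_maps(spec: NetworkBlobSpec) -> SpatialMapSet:
    """Render a blob spec into an M x N template map set.

    Deterministic given the spec.  Duplicate (identical) component maps are
    an error since they would make the stage-1 design singular.
    """
    n = spec.grid.n_voxels
    names = spec.names
    maps = np.zeros((len(names), n))
    for i, name in enumerate(names):
        for center, radius in spec.components[name]:
            maps[i, blob_mask(spec.grid, center, radius)] = spec.weight
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.array_equal(maps[i], maps[j]):
                raise ValueError(f"components {names[i]} and {names[j]} have identical maps")
    return SpatialMapSet(maps=maps, grid=spec.grid, component_names=names)


def component_region(spec: NetworkBlobSpec, component: str, blob_index: int) -> np.ndarray:
    """Flat mask of one blob of one component (e.g. the DMN's PCC node)."""
    blobs = spec.components[component]
    center, radius = blobs[blob_index]
    return blob_mask(spec.grid, center, radius)


def make_timecourses(
    m: int,
    t: int,
    tr: float,
    band: tuple[float, float] = (0.01, 0.1),
    seed=None,
    target_std: np.ndarray | float = 1.0,
    max_corr: float = 0.3,
    max_redraws: int = 100,
) -> np.ndarray:
    """Zero-mean band-limited Gaussian network timecourses, M x T.

    Rows are synthesized in the frequency domain (independent complex
    Gaussian coefficients inside the band, zero outside and at DC) and
    scaled to ``target_std`` (sample convention).  Sets whose largest
    pairwise |correlation| reaches ``max_corr`` are redrawn, keeping the
    networks' temporal dynamics close to independent.  Bit-reproducible
    from ``seed``.
    """
    if t < 2 * m:
        raise ValueError(f"need t >= 2*m, got t={t}, m={m}")
    lo, hi = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0.0 < lo < hi <= nyquist):
        raise ValueError(f"band {band} infeasible for TR={tr} (Nyquist {nyquist:.4g} Hz)")
    freqs = np.fft.rfftfreq(t, d=tr)
    in_band = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    if in_band.sum() < 2:
        raise ValueError(f"band {band} contains fewer than 2 frequency bins at T={t}, TR={tr}")
    rng = np.random.default_rng(seed)
    target = np.broadcast_to(np.asarray(target_std, dtype=float), (m,))
    if np.any(target <= 0):
        raise ValueError("target_std must be positive")
    k = int(in_band.sum())

    def draw_rows(n_rows: int) -> np.ndarray:
        spec = np.zeros((n_rows, freqs.size), dtype=complex)
        spec[:, in_band] = rng.standard_normal((n_rows, k)) + 1j * rng.standard_normal((n_rows, k))
        rows = np.fft.irfft(spec, n=t, axis=1)
        rows -= rows.mean(axis=1, keepdims=True)
        return rows / rows.std(axis=1, ddof=1)[:, np.newaxis]

    x = draw_rows(m)
    if m > 1:
        # redraw the single worst-offending row until all pairs decorrelate
        for _ in range(max_redraws):
            r = np.abs(np.corrcoef(x))
            np.fill_diagonal(r, 0.0)
            if r.max() < max_corr:
                break
            worst = int(np.argmax(r.max(axis=1)))
            x[worst] = draw_rows(1)[0]
        else:
            raise RuntimeError(f"could not draw timecourses with pairwise |r| < {max_corr}")
    return x * target[:, np.newaxis]


@dataclass
class EffectSpec:
    """One group manipulation.

    ``region`` is a flat boolean mask over the grid for the within-network
    and shape-swap kinds; ``target_component`` is the donor network of a
    shape swap.  ``group`` names the group the manipulation applies to.
    """

    kind: str
    component: int
    group: str
    factor: float = 1.0
    region: np.ndarray | None = None
    target_component: int | None = None

    def __post_init__(self):
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}; expected one of {EFFECT_KINDS}")
        if self.factor <= 0:
            raise ValueError("factor must be positive")
        if self.kind in ("within_network_amplitude", "shape_swap"):
            if self.region is None:
                raise ValueError(f"{self.kind} requires a region")
            self.region = np.asarray(self.region, dtype=bool)
        if self.kind == "shape_swap" and self.target_component is None:
            raise ValueError("shape_swap requires a target_component")


@dataclass
class CohortGroundTruth:
    """Complete manifest of a simulated cohort.

    ``timecourses`` holds each subject's *original* (pre-manipulation)
    M x T ground-truth network timecourses; manipulations are applied at
    signal-assembly time by :func:`apply_effects`.
    """

    maps: SpatialMapSet
    timecourses: list[np.ndarray]
    noise_std: np.ndarray
    mean_map: np.ndarray
    effects: list[EffectSpec]
    group_labels: list[str]
    seed: int
    tr: float = 2.0
    band: tuple[float, float] = (0.01, 0.1)
    network_spec: NetworkBlobSpec | None = None

    def __post_init__(self):
        n = self.maps.n_voxels
        self.noise_std = np.broadcast_to(np.asarray(self.noise_std, float), (n,)).copy()
        self.mean_map = np.broadcast_to(np.asarray(self.mean_map, float), (n,)).copy()
        if np.any(self.noise_std < 0):
            raise ValueError("noise_std must be nonnegative")
        if len(self.timecourses) != len(self.group_labels):
            raise ValueError("one group label per subject required")
        support = self.maps.maps != 0
        seen: dict[tuple[int, int], str] = {}
        for e in self.effects:
            if e.region is not None:
                if not np.all(support[e.component, e.region]):
                    raise ValueError(
                        f"effect region extends outside component "
                        f"{self.component_name(e.component)} support"
                    )
                for v in np.flatnonzero(e.region):
                    key = (e.component, int(v))
                    if key in seen:
                        raise ValueError(
                            f"conflicting effects ({seen[key]} and {e.kind}) on component "
                            f"{self.component_name(e.component)}, voxel {v}"
                        )
                    seen[key] = e.kind

    def component_name(self, idx: int) -> str:
        names = self.maps.component_names
        return names[idx] if names else str(idx)

    @property
    def n_subjects(self) -> int:
        return len(self.timecourses)

    def subjects_in_group(self, group: str) -> list[int]:
        return [i for i, g in enumerate(self.group_labels) if g == group]


def apply_effects(gt: CohortGroundTruth, subject: int) -> np.ndarray:
    """Noiseless, mean-free N x T signal for one subject, effects applied.

    Network-wide amplitude effects scale the whole component timecourse;
    within-network effects scale the timecourse used only at region voxels;
    shape swaps substitute the (unnormalized) donor timecourse at region
    voxels while keeping the source component's map weight.
    """
    group = gt.group_labels[subject]
    tau = gt.timecourses[subject].copy()
    active = [e for e in gt.effects if e.group == group]
    for e in active:
        if e.kind == "network_wide_amplitude":
            tau[e.component] *= e.factor
    s = gt.maps.maps  # M x N
    signal = s.T @ tau  # N x T
    for e in active:
        if e.kind == "within_network_amplitude":
            w = s[e.component, e.region]
            signal[e.region] += np.outer(w * (e.factor - 1.0), tau[e.component])
        elif e.kind == "shape_swap":
            w = s[e.component, e.region]
            signal[e.region] += np.outer(w, tau[e.target_component] - tau[e.component])
    return signal


def synthesize_subject(gt: CohortGroundTruth, subject: int, seed: int | None = None) -> BOLDDataset:
    """Simulated BOLD data for one subject: signal + noise + voxel means.

    Reproducible from ``(seed, subject)``; ``seed`` defaults to the
    cohort's seed.
    """
    signal = apply_effects(gt, subject)
    base = gt.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(entropy=base, spawn_key=(subject,)))
    noise = rng.standard_normal(signal.shape) * gt.noise_std[:, np.newaxis]
    data = signal + noise + gt.mean_map[:, np.newaxis]
    return BOLDDataset(
        data=data,
        grid=gt.maps.grid,
        tr=gt.tr,
        subject_id=f"sub{subject:03d}{gt.group_labels[subject]}",
    )


def default_cohort_config() -> dict:
    """Default cohort: 18+18 subjects, 8 networks, all three manipulations
    applied to Group B in a single cohort."""
    return {
        "grid_dims": [24, 24, 16],
        "voxel_size": [3.0, 3.0, 3.0],
        "n_per_group": 18,
        "t": 178,
        "tr": 2.0,
        "band": [0.01, 0.1],
        "noise_std": 0.5,
        "mean_value": 1000.0,
        "amplitude_range": [0.8, 1.2],
        "seed": 0,
        "effects": [
            {"kind": "network_wide_amplitude", "component": "MVN", "factor": 1.1, "group": "B"},
            {
                "kind": "within_network_amplitude",
                "component": "DMN",
                "region_blob": 0,  # the PCC node
                "factor": 1.5,
                "group": "B",
            },
            {
                "kind": "shape_swap",
                "component": "ECN",
                "region_blob": 1,  # the basal-ganglia/thalamus node
                "target_component": "LFPN",
                "group": "B",
            },
        ],
    }


_CONFIG_KEYS = {
    "grid_dims", "voxel_size", "n_per_group", "t", "tr", "band", "noise_std",
    "mean_value", "amplitude_range", "seed", "effects", "blobs", "blob_weight",
}


def _validate_config(config: dict) -> list[str]:
    problems = []
    for k in config:
        if k not in _CONFIG_KEYS:
            problems.append(f"unknown config key {k!r}")
    for k, pred, msg in [
        ("n_per_group", lambda v: int(v) >= 1, "must be a positive integer"),
        ("t", lambda v: int(v) >= 4, "must be an integer >= 4"),
        ("tr", lambda v: float(v) > 0, "must be positive"),
        ("noise_std", lambda v: np.all(np.asarray(v, float) >= 0), "must be nonnegative"),
    ]:
        if k in config:
            try:
                if not pred(config[k]):
                    problems.append(f"config[{k!r}] {msg}")
            except (TypeError, ValueError):
                problems.append(f"config[{k!r}] {msg}")
    for i, e in enumerate(config.get("effects", [])):
        if not isinstance(e, dict):
            problems.append(f"effects[{i}] must be a mapping")
            continue
        if e.get("kind") not in EFFECT_KINDS:
            problems.append(f"effects[{i}].kind must be one of {EFFECT_KINDS}")
        if "component" not in e:
            problems.append(f"effects[{i}] missing 'component'")
        if e.get("kind") == "shape_swap" and "target_component" not in e:
            problems.append(f"effects[{i}] (shape_swap) missing 'target_component'")
    return problems


def simulate_cohort(config: dict | None = None, seed: int | None = None) -> CohortGroundTruth:
    """Build the in-memory ground truth for a cohort configuration.

    ``seed`` overrides the config's seed.  Group A subjects come first,
    then Group B; per-subject timecourses and network amplitudes are drawn
    from a seed sequence keyed by (seed, subject).
    """
    cfg = default_cohort_config()
    if config:
        cfg.update(config)
    problems = _validate_config(cfg)
    if problems:
        raise ValueError("invalid cohort config:\n  " + "\n  ".join(problems))
    if seed is not None:
        cfg["seed"] = int(seed)
    grid = VolumeGrid(dims=tuple(cfg["grid_dims"]), voxel_size=tuple(cfg["voxel_size"]))
    blobs = cfg.get("blobs")
    spec = NetworkBlobSpec(
        grid=grid,
        components={k: [(tuple(c), float(r)) for c, r in v] for k, v in blobs.items()}
        if blobs
        else dict(DEFAULT_BLOBS),
        weight=float(cfg.get("blob_weight", 1.0)),
    )
    maps = make_network_maps(spec)
    names = maps.component_names or []
    m = maps.n_components
    n_per = int(cfg["n_per_group"])
    n_sub = 2 * n_per
    group_labels = ["A"] * n_per + ["B"] * n_per
    amp_lo, amp_hi = cfg["amplitude_range"]
    base = int(cfg["seed"])
    # Ground-truth amplitudes are matched across groups (subject i of Group A
    # and subject i of Group B share one amplitude draw, with independent
    # timecourse realizations): the injected manipulations are then the only
    # systematic group differences, and the non-manipulated networks show no
    # group amplitude differences, as in the reference regime this emulates.
    tcs = []
    for i in range(n_sub):
        amp_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=base, spawn_key=(10_000 + i % n_per,))
        )
        target = amp_rng.uniform(amp_lo, amp_hi, size=m)
        tc_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=base, spawn_key=(20_000 + i,))
        )
        tcs.append(
            make_timecourses(
                m, int(cfg["t"]), float(cfg["tr"]), tuple(cfg["band"]),
                seed=tc_rng, target_std=target,
            )
        )

    def resolve_component(ref) -> int:
        if isinstance(ref, str):
            if ref not in names:
                raise ValueError(f"unknown component {ref!r}; have {names}")
            return names.index(ref)
        return int(ref)

    effects = []
    for e in cfg["effects"]:
        comp = resolve_component(e["component"])
        region = None
        if "region_blob" in e:
            region = component_region(spec, names[comp], int(e["region_blob"]))
        elif "region" in e:
            region = np.asarray(e["region"], dtype=bool)
            if region.ndim == 3:
                region = flatten_volumes(region)
        target = resolve_component(e["target_component"]) if "target_component" in e else None
        effects.append(
            EffectSpec(
                kind=e["kind"], component=comp, group=e.get("group", "B"),
                factor=float(e.get("factor", 1.0)), region=region, target_component=target,
            )
        )
    return CohortGroundTruth(
        maps=maps,
        timecourses=tcs,
        noise_std=np.asarray(cfg["noise_std"], dtype=float),
        mean_map=float(cfg["mean_value"]),
        effects=effects,
        group_labels=group_labels,
        seed=base,
        tr=float(cfg["tr"]),
        band=tuple(cfg["band"]),
        network_spec=spec,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_cohort(config: dict | str | Path | None, outdir, seed: int | None = None) -> CohortGroundTruth:
    """Simulate a cohort and write all datasets plus a JSON manifest.

    ``config`` may be a mapping or a path to a YAML/JSON file.  Writes the
    template maps, one 4-D NIfTI per subject, and ``cohort_manifest.json``
    recording the seed, group labels, effects and file hashes.  Running
    twice with the same config and seed produces identical file hashes
    (NIfTI volumes are written uncompressed for this reason; gzip embeds a
    timestamp on some platforms).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    gt = simulate_cohort(config, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tmpl_path = outdir / "template_maps.nii"
    write_4d_image(gt.maps, tmpl_path)
    files = {"template_maps.nii": _sha256(tmpl_path)}
    names = gt.maps.component_names or []
    for i in range(gt.n_subjects):
        ds = synthesize_subject(gt, i)
        fname = f"sub{i:03d}{gt.group_labels[i]}.nii"
        write_4d_image(ds, outdir / fname)
        files[fname] = _sha256(outdir / fname)
    manifest = {
        "seed": gt.seed,
        "n_subjects": gt.n_subjects,
        "group_labels": gt.group_labels,
        "components": names,
        "tr": gt.tr,
        "band": list(gt.band),
        "effects": [
            {
                "kind": e.kind,
                "component": gt.component_name(e.component),
                "group": e.group,
                "factor": e.factor,
                "region_voxels": int(e.region.sum()) if e.region is not None else None,
                "target_component": gt.component_name(e.target_component)
                if e.target_component is not None
                else None,
            }
            for e in gt.effects
        ],
        "files": files,
    }
    (outdir / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2))
    return gt
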