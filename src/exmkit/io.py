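"""Image stack I/O, configuration-driven runs, and provenance.

Stacks are stored as multipage TIFF with a JSON sidecar (``<path>.json``)
carrying pixel size, axis order, channel names and an append-only provenance
log; pixel size is additionally written to the TIFF resolution tags.  A
missing pixel size reads back as ``None`` ("unknown") — downstream
nanometer-unit operations must refuse to run until it is set, never assume
a default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

VALID_AXES = set("TZCYX")


@dataclass
class ImageStack:
    """N-d image data with declared axis order and physical metadata."""

    data: np.ndarray
    axes: str                       # e.g. "TYX", "ZYX", "CYX", "YX"
    pixel_nm: float | None = None
    z_step_nm: float | None = None
    channel_names: list[str] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        ax = self.axes.upper()
        if len(ax) != self.data.ndim or not set(ax) <= VALID_AXES or \
                len(set(ax)) != len(ax):
            raise ValueError(
                f"axes {self.axes!r} do not match data ndim {self.data.ndim}")
        self.axes = ax
        if self.pixel_nm is not None and self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be > 0")

    def log(self, operation: str, **params) -> None:
        """Append one provenance record (append-only)."""
        self.provenance.append({"operation": operation, "params": params})

    def require_pixel_size(self) -> float:
        if self.pixel_nm is None:
            raise ValueError("pixel size unknown; set pixel_nm before "
                             "nanometer-unit operations")
        return self.pixel_nm


def write_stack(path, stack: ImageStack) -> Path:
    """Write a stack as multipage TIFF + JSON metadata sidecar."""
    path = Path(path)
    kwargs = {}
    if stack.pixel_nm is not None:
        per_cm = 1e7 / stack.pixel_nm
        kwargs["resolution"] = (per_cm, per_cm)
        kwargs["resolutionunit"] = "CENTIMETER"
    if stack.data.ndim >= 3:
        kwargs["photometric"] = "minisblack"
    tifffile.imwrite(path, stack.data, **kwargs)
    meta = {
        "axes": stack.axes,
        "pixel_nm": stack.pixel_nm,
        "z_step_nm": stack.z_step_nm,
        "channel_names": stack.channel_names,
        "provenance": stack.provenance,
        "dtype": str(stack.data.dtype),
        "shape": list(stack.data.shape),
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=1, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_stack(path, axes_hint: str | None = None) -> ImageStack:
    """Read a TIFF stack with its sidecar metadata if present.

    Without a sidecar, the axis order comes from ``axes_hint`` (or the
    tifffile series axes), and the pixel size from the TIFF resolution tags
    if they are set — otherwise it is reported as unknown (None), never
    silently defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        tif_axes = series.axes
        page = tf.pages[0]
        pixel_nm = None
        if "XResolution" in page.tags and page.tags["XResolution"].value:
            num, den = page.tags["XResolution"].value
            unit = page.tags.get("ResolutionUnit")
            if num and den and unit is not None:
                per_unit = num / den
                unit_nm = {2: 2.54e7, 3: 1e7}.get(getattr(unit.value, "value",
                                                          unit.value))
                if unit_nm and per_unit > 0:
                    pixel_nm = unit_nm / per_unit
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return ImageStack(data, meta["axes"], meta.get("pixel_nm"),
                          meta.get("z_step_nm"),
                          meta.get("channel_names", []),
                          meta.get("provenance", []))
    axes = axes_hint or _normalize_axes(tif_axes, data.ndim)
    return ImageStack(data, axes, pixel_nm)


def _normalize_axes(tif_axes: str, ndim: int) -> str:
    ax = "".join(a for a in tif_axes.upper().replace("S", "C").replace("I", "T")
                 if a in VALID_AXES)
    if len(ax) != ndim:
        ax = "TZC"[3 - (ndim - 2):] + "YX" if 2 <= ndim <= 5 else ""
    if len(ax) != ndim:
        raise ValueError(f"cannot infer axes for {ndim}-d data")
    return ax


# ---------------------------------------------------------------------------
# configuration-driven runs
# ---------------------------------------------------------------------------

CONFIG_VERSION = 1
KNOWN_STAGES = ("simulate", "sofi", "register", "distort", "ef", "retention",
                "resolution", "cilia", "chisq")


def run_config(config_path, out_dir=None) -> dict:
    """Execute a YAML-configured pipeline and write a JSON report.

    The config lists stages (each ``{stage: <name>, ...params}``) run in
    order; all stage names and referenced input paths are validated before
    any computation starts (fail-fast).  The report maps stage labels to
    their numeric results (EFs, RMS curves, retention fractions, resolution,
    defect tables) and records every seed used; identical configs + seeds
    produce identical reports.
    """
    import yaml

    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    if cfg.get("version", CONFIG_VERSION) != CONFIG_VERSION:
        raise ValueError(f"unsupported config version {cfg.get('version')}")
    stages = cfg.get("stages", [])
    out_dir = Path(out_dir or cfg.get("out_dir", config_path.parent))
    # validate everything up front
    for st in stages:
        name = st.get("stage")
        if name not in KNOWN_STAGES:
            raise ValueError(f"unknown stage {name!r}")
        unknown = set(st) - _STAGE_PARAMS[name] - {"stage", "label"}
        if unknown:
            raise ValueError(f"unknown parameter(s) {sorted(unknown)} "
                             f"for stage {name!r}")
        for key in ("input", "input_pre", "input_post", "input_a", "input_b"):
            if key in st and not Path(st[key]).exists():
                raise FileNotFoundError(f"stage {name!r}: missing input "
                                        f"{st[key]}")
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {"config": str(config_path), "version": CONFIG_VERSION,
              "seed": cfg.get("seed", 0), "stages": {}}
    for k, st in enumerate(stages):
        name = st["stage"]
        label = st.get("label", f"{name}_{k}")
        report["stages"][label] = _run_stage(name, st, cfg, out_dir)
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=1,
                                      default=_json_default, sort_keys=True))
    return report


_STAGE_PARAMS = {
    "simulate": {"type", "seed", "out", "params"},
    "sofi": {"input", "psf_fwhm_nm", "lag", "rl_iterations", "out"},
    "register": {"input_pre", "input_post", "seed"},
    "distort": {"input_pre", "input_post", "block_size", "search_radius",
                "n_pairs", "seed"},
    "ef": {"input_pre", "input_post", "threshold"},
    "retention": {"input_pre", "input_post", "ef", "background"},
    "resolution": {"input", "pixel_nm", "ef"},
    "cilia": {"input", "condition"},
    "chisq": {"table", "alpha", "yates"},
}


def _run_stage(name: str, st: dict, cfg: dict, out_dir: Path) -> dict:
    from . import defectstats, morphometry, regdist, resolution
    from . import sofi as sofimod
    from . import synthgen

    seed = int(st.get("seed", cfg.get("seed", 0)))
    if name == "simulate":
        scene = st.get("type", "blinking_movie")
        params = dict(st.get("params", {}))
        out = out_dir / st.get("out", f"{scene}.tif")
        if scene == "blinking_movie":
            n = int(params.pop("n_emitters", 20))
            shape = tuple(params.pop("shape", (64, 64)))
            amp = float(params.pop("amplitude", 200.0))
            em = synthgen.EmitterField.random(n, shape, amplitude=amp,
                                              seed=seed)
            movie, _ = synthgen.gen_blinking_movie(
                em, params.pop("psf_fwhm_nm", 300.0),
                params.pop("pixel_nm", 100.0), shape=shape, seed=seed,
                **params)
            write_stack(out, ImageStack(movie.data, "TYX", movie.pixel_nm))
        elif scene == "ring":
            img, truth = synthgen.gen_ring_structure(seed=seed, **params)
            write_stack(out, ImageStack(img, "YX",
                                        params.get("pixel_nm", 20.0)))
        else:
            raise ValueError(f"unknown scene type {scene!r}")
        return {"scene": scene, "seed": seed, "path": out.name}
    if name == "sofi":
        stk = read_stack(st["input"])
        movie = sofimod.BlinkingMovie(stk.data, stk.require_pixel_size())
        img, log = sofimod.sofi_pipeline(
            movie, st["psf_fwhm_nm"], lag=int(st.get("lag", 1)),
            rl_iterations=int(st.get("rl_iterations", 50)))
        out = out_dir / st.get("out", "sofi.tif")
        write_stack(out, ImageStack(img, "YX", log["pixel_nm_effective"]))
        return {"path": out.name, "lag": log["lag"],
                "pixel_nm_effective": log["pixel_nm_effective"]}
    if name == "register":
        pre = read_stack(st["input_pre"])
        post = read_stack(st["input_post"])
        t, aligned, m, mask = regdist.register_expansion_pair(
            pre.data, post.data, seed=seed)
        return {"ef": t.scale, "rotation_deg": t.rotation_deg,
                "translation_px": list(t.translation),
                "n_inliers": int(mask.sum()), "seed": seed,
                "scale_frame": "post relative to pre (expanded/biological)"}
    if name == "distort":
        pre = read_stack(st["input_pre"])
        post = read_stack(st["input_post"])
        t, aligned, _, _ = regdist.register_expansion_pair(pre.data, post.data,
                                                           seed=seed)
        fld = regdist.estimate_distortion_field(
            pre.data, aligned, block_size=int(st.get("block_size", 32)),
            search_radius=int(st.get("search_radius", 8)))
        curve = regdist.rms_error_curve(
            fld, n_pairs=int(st.get("n_pairs", 100000)),
            pixel_nm=pre.require_pixel_size(), ef=1.0, seed=seed)
        return {"ef": t.scale, "length_um": curve.length_um,
                "rms_um": curve.rms_um, "counts": curve.counts,
                "seed": seed, "scale_frame": "biological (pre-expansion)"}
    if name == "ef":
        pre = read_stack(st["input_pre"])
        post = read_stack(st["input_post"])
        thr = st.get("threshold", "otsu")
        ef = morphometry.ef_from_areas(
            morphometry.segment_nuclei(pre.data, threshold=thr),
            morphometry.segment_nuclei(post.data, threshold=thr))
        return {"ef": ef, "method": "nuclear areas"}
    if name == "retention":
        pre = read_stack(st["input_pre"])
        post = read_stack(st["input_post"])
        res = morphometry.retention(pre.data, post.data, float(st["ef"]),
                                    background=st.get("background", "mode"))
        return {"retention": res.retention, "ef": res.ef,
                "above_one": res.above_one}
    if name == "resolution":
        stk = read_stack(st["input"])
        px = st.get("pixel_nm", stk.pixel_nm)
        est = resolution.decorrelation_resolution(stk.data, pixel_nm=px,
                                                  ef=float(st.get("ef", 1.0)))
        out = {"kc": est.kc}
        if px is not None:
            out["resolution_nm"] = est.resolution_nm
            out["biological_resolution_nm"] = est.biological_resolution_nm
            out["ef"] = est.ef
        return out
    if name == "cilia":
        stk = read_stack(st["input"])
        imgs = stk.data if stk.data.ndim == 3 else stk.data[None]
        counts = defectstats.assess_cilia(
            {st.get("condition", "default"): list(imgs)})
        return {"conditions": counts.conditions,
                "normal": counts.normal, "defective": counts.defective,
                "unscorable": counts.unscorable}
    if name == "chisq":
        res = defectstats.chisq_proportions(
            st["table"], alpha=float(st.get("alpha", 0.05)),
            yates=bool(st.get("yates", False)))
        return {"statistic": res.statistic, "df": res.df,
                "p_value": res.p_value, "significant": res.significant,
                "low_expected": res.low_expected}
    raise ValueError(f"unknown stage {name!r}")
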