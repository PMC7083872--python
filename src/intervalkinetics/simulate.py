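"""Synthetic ground-truth data for the interval-imaging pipeline.

Two levels of realism are provided:

* :func:`simulate_events` draws binding-event tables directly from the
  kinetic model — the statistical object the CRTD fitter consumes — with
  per-event ground-truth labels.
* :func:`simulate_movie` renders full two-phase image stacks (bleach-down
  phase followed by the single-molecule phase) with diffraction-limited
  foci on noisy elliptical cells, so the detection/linking stage can be
  benchmarked against a known emitter table.

Frame-discretisation convention: a molecule is counted in a frame only if
it remains bound through the frame's full integration window, and
photobleaching is tested once per illuminated frame (per-frame survival
``exp(-k_b * tau_int)``).  Under this convention the number of observed
frames M satisfies ``P(M >= m) = sum_i A_i exp(-k_eff_i * m * tau_tl)``,
exactly the mixture the fitter assumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import AcquisitionProtocol, KineticModel

__all__ = ["simulate_events", "simulate_movie", "GroundTruthMovie", "EVENT_COLUMNS"]

EVENT_COLUMNS = [
    "acquisition_id",
    "tau_tl_s",
    "start_frame",
    "n_frames",
    "x_px",
    "y_px",
    "wall_clock_s",
    "population_index",
]


def _require_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is required; simulations must be reproducible")
    return np.random.default_rng(seed)


def _draw_observed_frames(
    rng: np.random.Generator,
    model: KineticModel,
    tau_tl: float,
    tau_int: float,
    n_sm_frames: int,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (population index, observed frame count) for ``n`` events.

    Frame counts are unconditional: events that fail to survive a single
    full frame come back as 0 observed frames (undetectable).
    """
    amps = np.asarray(model.amplitudes)
    rates = np.asarray(model.off_rates)
    pop = rng.choice(len(amps), size=n, p=amps)
    t_bind = rng.exponential(1.0 / rates[pop])
    m_bind = np.floor(t_bind / tau_tl).astype(np.int64)
    if model.k_b > 0:
        t_bleach = rng.exponential(1.0 / model.k_b, size=n)
        m_bleach = np.floor(t_bleach / tau_int).astype(np.int64)
    else:
        m_bleach = np.full(n, np.iinfo(np.int64).max)
    observed = np.minimum(np.minimum(m_bind, m_bleach), n_sm_frames)
    return pop, observed


def simulate_events(
    model: KineticModel,
    protocol: AcquisitionProtocol,
    n_events_per_tau: int,
    seed: int,
    *,
    events_per_acquisition: int = 50,
    t0_s: float = 0.0,
) -> pd.DataFrame:
    """Simulate a table of detected binding events for every tau_tl.

    For each event a kinetic population is drawn with probability equal to
    its amplitude, the binding time is exponential with that population's
    lifetime, and the fluorophore survives each illuminated frame with
    probability ``exp(-k_b * tau_int)``.  Events lasting zero full frames
    are undetectable and redrawn, so the table contains exactly
    ``n_events_per_tau`` detected events per time-lapse setting (mirroring
    published event counts, which are counts of detected events).  Dwells
    are right-censored at ``n_sm_frames``.

    Events are grouped into acquisitions of at most
    ``events_per_acquisition`` events; within one acquisition each event
    gets a distinct start frame, so wall-clock stamps are strictly
    increasing and spaced in multiples of tau_tl.  Acquisitions are
    scheduled in rounds that cycle through the whole tau_tl grid (one
    video per setting per round), mirroring how interval imaging is run
    in practice and making time-windowed analyses meaningful.  ``t0_s``
    offsets all wall-clock times.

    Returns a DataFrame with columns ``acquisition_id, tau_tl_s,
    start_frame, n_frames, x_px, y_px, wall_clock_s, population_index``.
    """
    if n_events_per_tau < 1:
        raise ValueError("n_events_per_tau must be >= 1")
    rng = _require_seed(seed)
    events_per_acquisition = min(events_per_acquisition, protocol.n_sm_frames)
    h, w = protocol.frame_shape
    per_tau: dict[float, dict] = {}
    for tau_tl in protocol.tau_tl_grid:
        pops = np.empty(0, dtype=np.int64)
        obs = np.empty(0, dtype=np.int64)
        # rejection-sample until n detected (>= 1 frame) events accumulate
        while obs.size < n_events_per_tau:
            deficit = n_events_per_tau - obs.size
            n_draw = max(int(deficit * 1.5) + 16, deficit)
            p, o = _draw_observed_frames(
                rng, model, tau_tl, protocol.tau_int, protocol.n_sm_frames, n_draw
            )
            keep = o >= 1
            pops = np.concatenate([pops, p[keep]])
            obs = np.concatenate([obs, o[keep]])
        n = n_events_per_tau
        acq_index = np.arange(n) // events_per_acquisition
        start_frame = np.empty(n, dtype=np.int64)
        for a in range(int(acq_index.max()) + 1):
            sel = acq_index == a
            start_frame[sel] = np.sort(
                rng.choice(protocol.n_sm_frames, size=int(sel.sum()),
                           replace=False)
            )
        per_tau[tau_tl] = {
            "pops": pops[:n], "obs": obs[:n], "acq_index": acq_index,
            "start_frame": start_frame,
            "n_acq": int(acq_index.max()) + 1,
            "t_acq": np.empty(int(acq_index.max()) + 1, dtype=float),
        }

    # schedule acquisitions in rounds cycling through the tau_tl grid
    clock = float(t0_s)
    max_rounds = max(d["n_acq"] for d in per_tau.values())
    for r in range(max_rounds):
        for tau_tl in protocol.tau_tl_grid:
            d = per_tau[tau_tl]
            if r < d["n_acq"]:
                d["t_acq"][r] = clock
                clock += (
                    protocol.n_bleach_frames * protocol.tau_int
                    + protocol.n_sm_frames * tau_tl
                )

    frames: list[pd.DataFrame] = []
    for tau_tl in protocol.tau_tl_grid:
        d = per_tau[tau_tl]
        n = n_events_per_tau
        wall_clock = (
            d["t_acq"][d["acq_index"]]
            + protocol.n_bleach_frames * protocol.tau_int
            + d["start_frame"] * tau_tl
        )
        acq_ids = np.array(
            [f"tl{tau_tl:g}_acq{a:04d}" for a in d["acq_index"]], dtype=object
        )
        frames.append(
            pd.DataFrame(
                {
                    "acquisition_id": acq_ids,
                    "tau_tl_s": tau_tl,
                    "start_frame": d["start_frame"],
                    "n_frames": d["obs"],
                    "x_px": rng.uniform(0, w, size=n),
                    "y_px": rng.uniform(0, h, size=n),
                    "wall_clock_s": wall_clock,
                    "population_index": d["pops"] + 1,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class GroundTruthMovie:
    """Synthetic image stack with full emitter ground truth.

    ``stack`` is a uint16 array of shape (n_frames, H, W) covering phase I
    (bleach-down) followed by phase II (single-molecule tracking at one
    tau_tl).  ``emitter_table`` lists every rendered focus as
    (frame, x_px, y_px, intensity, emitter_id); ``event_table`` carries the
    phase-II binding events in the standard event-table schema.
    """

    stack: np.ndarray
    emitter_table: pd.DataFrame
    event_table: pd.DataFrame
    cell_masks: np.ndarray
    protocol: AcquisitionProtocol
    tau_tl: float
    seed: int

    def save(self, path: str | Path) -> None:
        """Write TIFF stack + CSV tables + JSON sidecar next to ``path``."""
        import tifffile

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, self.stack)
        stem = path.with_suffix("")
        tifffile.imwrite(
            stem.parent / (stem.name + "_masks.tif"), self.cell_masks.astype(np.uint16)
        )
        self.emitter_table.to_csv(stem.parent / (stem.name + "_emitters.csv"), index=False)
        self.event_table.to_csv(stem.parent / (stem.name + "_events.csv"), index=False)
        sidecar = {
            "protocol": self.protocol.to_dict(),
            "tau_tl_s": self.tau_tl,
            "seed": self.seed,
            "emitter_table": stem.name + "_emitters.csv",
            "event_table": stem.name + "_events.csv",
            "cell_masks": stem.name + "_masks.tif",
        }
        (stem.parent / (stem.name + ".json")).write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )


def _make_cell_masks(
    rng: np.random.Generator, shape: tuple[int, int], cells: int
) -> np.ndarray:
    """Non-overlapping elliptical cell footprints on a dark background."""
    h, w = shape
    masks = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    placed = 0
    attempts = 0
    while placed < cells and attempts < cells * 50:
        attempts += 1
        a = rng.uniform(0.18, 0.28) * min(h, w)  # semi-major (rod length)
        b = rng.uniform(0.06, 0.10) * min(h, w)  # semi-minor (rod width)
        cy = rng.uniform(a, h - a)
        cx = rng.uniform(a, w - a)
        theta = rng.uniform(0, np.pi)
        dx = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        dy = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        ellipse = (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
        if np.any(masks[ellipse] != 0):
            continue
        placed += 1
        masks[ellipse] = placed
    if placed < cells:
        warnings.warn(
            f"could only place {placed}/{cells} non-overlapping cells", stacklevel=2
        )
    return masks


def _render_gaussians(
    frame: np.ndarray, xs: np.ndarray, ys: np.ndarray, fluxes: np.ndarray, sigma: float
) -> None:
    """Add 2-D Gaussian spots (total flux = ``fluxes``) to ``frame`` in place."""
    h, w = frame.shape
    r = int(np.ceil(4 * sigma))
    for x, y, flux in zip(xs, ys, fluxes):
        x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
        y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        gx = np.arange(x0c, x1c)
        gy = np.arange(y0c, y1c)
        gxx, gyy = np.meshgrid(gx, gy)
        g = np.exp(-((gxx - x) ** 2 + (gyy - y) ** 2) / (2 * sigma**2))
        frame[y0c:y1c, x0c:x1c] += flux * g / (2 * np.pi * sigma**2)


def simulate_movie(
    model: KineticModel,
    protocol: AcquisitionProtocol,
    cells: int,
    emitters_per_cell: int,
    psf_sigma: float = 1.2,
    background_mean: float = 100.0,
    noise_sd: float = 3.0,
    seed: int | None = None,
    *,
    tau_tl: float | None = None,
    spot_flux: float = 2000.0,
    cell_background: float = 30.0,
) -> GroundTruthMovie:
    """Render a two-phase synthetic movie at one time-lapse setting.

    Phase I starts with a dense emitter population (5x the phase-II count)
    that bleaches under continuous illumination; phase II renders
    individual binding events drawn from :func:`simulate_events`, each a
    2-D Gaussian of total flux ``spot_flux`` while bound and unbleached.
    Pixel noise is Poisson (shot) plus Gaussian (read); output is uint16.
    """
    if psf_sigma < 0.8:
        raise ValueError("psf_sigma must be >= 0.8 px (diffraction limit)")
    if background_mean <= 0:
        raise ValueError("background_mean must be positive")
    rng = _require_seed(seed)
    tau_tl = float(tau_tl if tau_tl is not None else protocol.tau_tl_grid[0])
    h, w = protocol.frame_shape
    masks = _make_cell_masks(rng, (h, w), cells)
    n_total = protocol.n_bleach_frames + protocol.n_sm_frames

    # phase-II binding events, positioned uniformly inside cells
    records = []
    if emitters_per_cell > 0:
        single_tau_protocol = AcquisitionProtocol(
            tau_int=protocol.tau_int,
            tau_tl_grid=(tau_tl,),
            n_bleach_frames=protocol.n_bleach_frames,
            n_sm_frames=protocol.n_sm_frames,
            frame_shape=protocol.frame_shape,
            pixel_size_nm=protocol.pixel_size_nm,
        )
        events = simulate_events(
            model,
            single_tau_protocol,
            n_events_per_tau=cells * emitters_per_cell,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cell_ids = np.unique(masks[masks > 0])
        in_cell = np.argwhere(masks > 0)
        pick = rng.integers(0, len(in_cell), size=len(events))
        jitter = rng.uniform(-0.5, 0.5, size=(len(events), 2))
        events["y_px"] = in_cell[pick, 0] + jitter[:, 0]
        events["x_px"] = in_cell[pick, 1] + jitter[:, 1]
        del cell_ids
        # warn on crowding (linking-radius collisions)
        if len(events) > 1:
            per_frame = len(events) * 1.0 / protocol.n_sm_frames
            area = (masks > 0).sum()
            if per_frame > 0 and np.sqrt(area / max(per_frame, 1)) < 4:
                warnings.warn("emitter density risks linking collisions", stacklevel=2)
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)

    # phase-I bleach-down emitters: all present at frame 0, geometric survival
    n_dense = 5 * cells * emitters_per_cell
    if n_dense > 0:
        in_cell = np.argwhere(masks > 0)
        pick = rng.integers(0, len(in_cell), size=n_dense)
        dense_xy = in_cell[pick][:, ::-1] + rng.uniform(-0.5, 0.5, size=(n_dense, 2))
        if model.k_b > 0:
            dense_frames = np.floor(
                rng.exponential(1.0 / model.k_b, size=n_dense) / protocol.tau_int
            ).astype(int)
        else:
            dense_frames = np.full(n_dense, protocol.n_bleach_frames)
        dense_frames = np.clip(dense_frames, 0, protocol.n_bleach_frames)

    stack = np.zeros((n_total, h, w), dtype=np.uint16)
    emitter_rows = []
    for f in range(n_total):
        frame = np.full((h, w), float(background_mean))
        frame[masks > 0] += cell_background
        if n_dense > 0 and f < protocol.n_bleach_frames:
            alive = dense_frames > f
            _render_gaussians(
                frame,
                dense_xy[alive, 0],
                dense_xy[alive, 1],
                np.full(int(alive.sum()), spot_flux),
                psf_sigma,
            )
        if f >= protocol.n_bleach_frames and len(events):
            sm_frame = f - protocol.n_bleach_frames
            active = (events["start_frame"] <= sm_frame) & (
                sm_frame < events["start_frame"] + events["n_frames"]
            )
            sub = events.loc[active]
            _render_gaussians(
                frame,
                sub["x_px"].to_numpy(),
                sub["y_px"].to_numpy(),
                np.full(len(sub), spot_flux),
                psf_sigma,
            )
            for eid, row in sub.iterrows():
                emitter_rows.append(
                    (f, row["x_px"], row["y_px"], spot_flux, int(eid))
                )
        noisy = rng.poisson(np.clip(frame, 0, None)) + rng.normal(
            0, noise_sd, size=frame.shape
        )
        stack[f] = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)

    emitter_table = pd.DataFrame(
        emitter_rows, columns=["frame", "x_px", "y_px", "intensity", "emitter_id"]
    )
    return GroundTruthMovie(
        stack=stack,
        emitter_table=emitter_table,
        event_table=events,
        cell_masks=masks,
        protocol=protocol,
        tau_tl=tau_tl,
        seed=int(seed),
    )
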