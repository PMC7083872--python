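"""Published ground-truth parameter sets for validation by simulation.

Reported interval-imaging measurements of YPet-tagged nucleotide excision
repair proteins (UvrA, Mfd) in live E. coli provide lifetime mixtures,
amplitudes, bleach rates, and compiled event counts for a panel of
genetic backgrounds.  Because the underlying raw movies are not publicly
deposited, these parameter sets serve as simulation ground truths: events
are generated from them and the pipeline must recover the published
values within the published bootstrap uncertainties.

Each entry records the kinetic model (fast population first), the
published per-parameter standard deviations, the compiled detected-event
count, and which time-lapse grid the measurement used.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetics import DEFAULT_TAU_TL_GRID, UV_TAU_TL_GRID, AcquisitionProtocol, KineticModel

__all__ = [
    "ReferenceMeasurement",
    "REFERENCE_MEASUREMENTS",
    "reference_protocol",
    "simulate_and_refit",
]


@dataclass(frozen=True)
class ReferenceMeasurement:
    """One published strain measurement usable as simulation ground truth."""

    label: str
    amplitudes: tuple[float, ...]          # fractions, fast first
    lifetimes_s: tuple[float, ...]         # seconds, ascending
    lifetime_sd_s: tuple[float, ...]       # published bootstrap SDs
    amplitude_sd_pct: tuple[float, ...]
    k_b_per_s: float
    k_b_sd_per_s: float
    n_events: int
    n_events_published: bool
    tau_tl_grid: tuple[float, ...] = DEFAULT_TAU_TL_GRID

    @property
    def model(self) -> KineticModel:
        return KineticModel.from_lifetimes(self.amplitudes, self.lifetimes_s,
                                           self.k_b_per_s)

    @property
    def protocol(self) -> AcquisitionProtocol:
        return reference_protocol(self.tau_tl_grid)


def reference_protocol(
    tau_tl_grid: tuple[float, ...] = DEFAULT_TAU_TL_GRID,
) -> AcquisitionProtocol:
    """Standard two-phase acquisition: 50 bleach + 100 SM frames, 0.1 s."""
    return AcquisitionProtocol(
        tau_int=0.1, tau_tl_grid=tau_tl_grid, n_bleach_frames=50, n_sm_frames=100
    )


REFERENCE_MEASUREMENTS: dict[str, ReferenceMeasurement] = {
    # UvrA-YPet from plasmid in cells lacking uvrA, uvrB and mfd:
    # two populations an order of magnitude apart.
    "uvrA_no_uvrB_no_mfd_plasmid": ReferenceMeasurement(
        label="ΔuvrA ΔuvrB Δmfd / pUvrA-YPet",
        amplitudes=(0.72, 0.28),
        lifetimes_s=(1.6, 24.0),
        lifetime_sd_s=(0.1, 1.0),
        amplitude_sd_pct=(2.0, 2.0),
        k_b_per_s=5.5,
        k_b_sd_per_s=0.1,
        n_events=34927,
        n_events_published=True,
    ),
    # UvrA lacking the UvrB/Mfd interaction interface (residues 131-250):
    # a single long-lived population.
    "uvrA_d131_250": ReferenceMeasurement(
        label="ΔuvrA / pUvrA(Δ131–250)-YPet",
        amplitudes=(1.0,),
        lifetimes_s=(29.7,),
        lifetime_sd_s=(0.8,),
        amplitude_sd_pct=(0.0,),
        k_b_per_s=5.2,
        k_b_sd_per_s=0.05,
        n_events=88232,
        n_events_published=True,
    ),
    # UvrA-YPet with the loading-deficient UvrB beta-hairpin mutant.
    "uvrA_uvrB_betahairpin_no_mfd": ReferenceMeasurement(
        label="uvrA-YPet uvrB(ΔβHG) Δmfd",
        amplitudes=(1.0,),
        lifetimes_s=(148.0,),
        lifetime_sd_s=(36.0,),
        amplitude_sd_pct=(0.0,),
        k_b_per_s=6.0,
        k_b_sd_per_s=0.2,
        n_events=16353,
        n_events_published=True,
    ),
    # UvrA-YPet in cells lacking UvrB: Mfd arrests UvrA on DNA.  No event
    # count is published for this strain; 10,000 is the scaled stand-in.
    "uvrA_no_uvrB": ReferenceMeasurement(
        label="uvrA-YPet ΔuvrB",
        amplitudes=(1.0,),
        lifetimes_s=(97.0,),
        lifetime_sd_s=(18.0,),
        amplitude_sd_pct=(0.0,),
        k_b_per_s=7.3,
        k_b_sd_per_s=0.1,
        n_events=10000,
        n_events_published=False,
    ),
    # UvrA-YPet in TCR-deficient (mfd-) cells.
    "uvrA_no_mfd": ReferenceMeasurement(
        label="uvrA-YPet Δmfd",
        amplitudes=(0.78, 0.22),
        lifetimes_s=(1.5, 8.7),
        lifetime_sd_s=(0.1, 0.4),
        amplitude_sd_pct=(2.0, 2.0),
        k_b_per_s=6.3,
        k_b_sd_per_s=0.2,
        n_events=29743,
        n_events_published=True,
    ),
    # UvrA-YPet in wild-type cells.
    "uvrA_wild_type": ReferenceMeasurement(
        label="uvrA-YPet",
        amplitudes=(0.79, 0.21),
        lifetimes_s=(1.9, 12.0),
        lifetime_sd_s=(0.2, 0.8),
        amplitude_sd_pct=(2.0, 2.0),
        k_b_per_s=7.2,
        k_b_sd_per_s=0.2,
        n_events=20111,
        n_events_published=True,
    ),
    # Mfd-YPet after 20 J/m2 UVC, temporally averaged, on the compressed
    # 5-point UV time-lapse grid.
    "mfd_uv_averaged": ReferenceMeasurement(
        label="mfd-YPet, 20 J/m2 UVC (temporally averaged)",
        amplitudes=(1.0,),
        lifetimes_s=(12.0,),
        lifetime_sd_s=(0.6,),
        amplitude_sd_pct=(0.0,),
        k_b_per_s=6.0,
        k_b_sd_per_s=0.1,
        n_events=14553,
        n_events_published=True,
        tau_tl_grid=UV_TAU_TL_GRID,
    ),
}


def simulate_and_refit(
    measurement: ReferenceMeasurement,
    seed: int,
    n_total: int | None = None,
):
    """Round-trip validation: simulate a measurement, then re-fit it.

    Draws the measurement's compiled event count (allocated equally across
    its time-lapse grid) from the published ground-truth parameters, builds
    the CRTDs, and runs the global fit at the published model order.
    Returns the :class:`~intervalkinetics.fitcrtd.GlobalFitResult`; its
    parameters should match the generating values within the published
    bootstrap uncertainties.
    """
    from .fitcrtd import build_crtds, fit_global
    from .simulate import simulate_events

    n = int(n_total if n_total is not None else measurement.n_events)
    protocol = measurement.protocol
    n_per_tau = max(int(round(n / len(protocol.tau_tl_grid))), 1)
    events = simulate_events(measurement.model, protocol, n_per_tau, seed=seed)
    crtds = build_crtds(events, protocol)
    return fit_global(crtds, protocol, model_order=len(measurement.amplitudes))
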