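"""Synthetic session generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes:

* homogeneous / inhomogeneous Poisson spike trains with von Mises phase
  locking to a sinusoidal stimulus (Lewis–Shedler thinning);
* LFP with a 1/f² spectral background, optionally carrying injected
  low-frequency-phase → high-frequency-amplitude coupling;
* a sinusoidal stimulation artifact whose per-channel amplitude follows a
  planar spatial gradient across the electrode array, from which the field
  estimator can recover the injected field magnitude.

Every generator takes an explicit seed or ``numpy.random.Generator`` and is
deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import i0

from .core import TWO_PI, Recording, SpikeTrain, StimProtocol, spiketrains_to_csv

__all__ = [
    "SynthConfig",
    "gen_stim_waveform",
    "gen_spiketrain",
    "gen_lfp",
    "inject_artifact",
    "gen_session",
    "Session",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic session.

    Defaults mirror the recording setup the analysis is designed for: a 4×4
    array on 0.5 mm pitch, log-normally distributed baseline rates with a
    median of about 1 Hz, and a 1/f² LFP background.

    ``frac_entrained`` / ``frac_excited`` / ``frac_suppressed`` split neurons
    into ground-truth response classes (the remainder are unaffected);
    entrained neurons lock with concentration ``kappa``, excited/suppressed
    neurons scale their stimulation-period rate by ``excite_factor`` /
    ``suppress_factor``.
    """

    n_channels: int = 16
    grid_shape: tuple[int, int] = (4, 4)
    pitch: float = 0.5  # mm
    duration: float = 180.0  # s
    n_neurons_per_channel: int = 4
    baseline_rate: float = 1.0  # Hz, log-normal median across neurons
    rate_sigma: float = 0.7  # log-normal sigma of baseline rates
    kappa: float = 2.0  # von Mises concentration of entrained neurons
    preferred_phase: float = 3 * np.pi / 2  # radians
    frac_entrained: float = 0.0
    frac_excited: float = 0.0
    frac_suppressed: float = 0.0
    excite_factor: float = 2.0
    suppress_factor: float = 0.5
    pac_spec: tuple[float, float, float] | None = None  # (lf Hz, hf Hz, depth)
    one_over_f_exponent: float = 2.0
    background_std: float = 15.0  # µV, 1/f² LFP background
    lfp_highpass: float = 0.3  # Hz, lower edge of the LFP band
    sensor_noise_std: float = 4.0  # µV, broadband electrode/amplifier noise
    lf_osc_amplitude: float = 4.0  # µV, PAC phase-providing oscillation
    lf_phase_diffusion: float = 0.5  # rad²/s, phase random walk of the LF rhythm
    hf_carrier_amplitude: float = 3.0  # µV RMS, PAC carrier before modulation
    hf_band_sigma: float = 4.0  # Hz, spectral width of the narrowband carrier
    artifact_gradient: tuple[float, float] = (0.0, 0.0)  # (g_x, g_y) mV/mm
    artifact_base_amplitude: float = 500.0  # µV at the array corner
    lfp_rate: float = 1200.0  # Hz
    mua_rate: float = 24000.0  # Hz
    mua_noise_std: float = 5.0  # µV
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.kappa < 0:
            raise ValueError("baseline_rate and kappa must be non-negative")
        if self.pac_spec is not None and not 0.0 <= self.pac_spec[2] <= 1.0:
            raise ValueError("modulation depth must lie in [0, 1]")
        if self.grid_shape[0] * self.grid_shape[1] != self.n_channels:
            raise ValueError("grid_shape must tile n_channels")

    def geometry(self) -> list[tuple[int, int]]:
        rows, cols = self.grid_shape
        return [(r, c) for r in range(rows) for c in range(cols)]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_stim_waveform(
    protocol: StimProtocol, duration: float, scale: float = 1.0
) -> np.ndarray:
    """Commanded stimulus trace: ``scale·sin(2πf(t−onset)+φ₀)`` in the
    stimulation window, zero outside.

    Sampled at ``protocol.sampling_rate``; ``duration`` must cover the
    protocol offset.
    """
    if duration < protocol.offset:
        raise ValueError("duration must cover the protocol offset")
    t = np.arange(int(round(duration * protocol.sampling_rate))) / protocol.sampling_rate
    wav = np.zeros_like(t)
    on = (t >= protocol.onset) & (t < protocol.offset)
    x = TWO_PI * protocol.frequency * (t[on] - protocol.onset) + protocol.phase_at_onset
    wav[on] = scale * np.sin(x)
    return wav


def gen_spiketrain(
    rate: float,
    duration: float,
    kappa: float,
    preferred_phase: float,
    protocol: StimProtocol | None,
    seed,
    neuron_id: str = "n0",
    channel_id: int = 0,
    stim_rate_factor: float = 1.0,
) -> SpikeTrain:
    """Poisson spike train, phase-locked to the stimulus during stimulation.

    Outside the stimulation window the train is homogeneous Poisson at
    ``rate``.  Inside it follows an inhomogeneous Poisson process with
    intensity ::

        λ(t) = r_stim · exp(κ·cos(φ(t) − preferred_phase)) / I0(κ)

    where ``r_stim = rate · stim_rate_factor`` and ``φ(t)`` is the stimulus
    phase.  The von Mises modulation is normalized, so the time-averaged
    intensity equals ``r_stim``.  Realized by Lewis–Shedler thinning with
    bound ``r_stim·exp(κ)/I0(κ)``.
    """
    if rate < 0 or kappa < 0:
        raise ValueError("rate and kappa must be non-negative")
    rng = _as_rng(seed)
    if rate == 0 or duration <= 0:
        return SpikeTrain(neuron_id, channel_id, np.empty(0))

    r_stim = rate * stim_rate_factor
    segments: list[np.ndarray] = []
    bounds: list[tuple[float, float, bool]] = []
    if protocol is None:
        bounds = [(0.0, duration, False)]
    else:
        on = max(0.0, min(protocol.onset, duration))
        off = max(0.0, min(protocol.offset, duration))
        if on > 0:
            bounds.append((0.0, on, False))
        if off > on:
            bounds.append((on, off, True))
        if duration > off:
            bounds.append((off, duration, False))

    for start, stop, stim in bounds:
        span = stop - start
        if span <= 0:
            continue
        if not stim or kappa == 0:
            r = r_stim if stim else rate
            if r == 0:
                continue
            n = rng.poisson(r * span)
            segments.append(np.sort(rng.uniform(start, stop, size=n)))
        else:
            lam_max = r_stim * np.exp(kappa) / i0(kappa)
            n = rng.poisson(lam_max * span)
            cand = np.sort(rng.uniform(start, stop, size=n))
            phi = protocol.phase(cand)
            lam = r_stim * np.exp(kappa * np.cos(phi - preferred_phase)) / i0(kappa)
            keep = rng.uniform(size=n) < lam / lam_max
            segments.append(cand[keep])

    times = np.concatenate(segments) if segments else np.empty(0)
    times = np.unique(times)  # strictly increasing; ties have measure zero
    return SpikeTrain(neuron_id, channel_id, times)


def _one_over_f_noise(
    n: int, rate: float, exponent: float, std: float, rng, highpass: float = 0.3
) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ 1/f^exponent above
    ``highpass`` (the lower edge of the recorded LFP band; without it the
    variance of a 1/f² process concentrates in sub-0.1 Hz drift that real
    acquisition filters remove).

    White noise is shaped in the frequency domain by f^(−exponent/2) (the
    amplitude spectrum), giving the exact target slope; bins below the
    high-pass edge are zeroed and the result rescaled to the requested
    standard deviation.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.zeros_like(freqs)
    keep = freqs >= highpass
    shape[keep] = freqs[keep] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * shape, n=n)
    sd = out.std()
    if sd > 0:
        out *= std / sd
    return out


def _narrowband_noise(
    n: int, rate: float, center: float, sigma: float, rms: float, rng
) -> np.ndarray:
    """Gaussian noise confined to a Gaussian spectral band around ``center``."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    out = np.fft.irfft(spec * np.exp(-0.5 * ((freqs - center) / sigma) ** 2), n=n)
    sd = out.std()
    return out * (rms / sd) if sd > 0 else out


def gen_lfp(
    config: SynthConfig, duration: float | None = None, seed=None
) -> Recording:
    """Multi-channel LFP-band recording: 1/f² background, optional PAC.

    Each channel is 1/f²-shaped Gaussian noise plus a broadband sensor-noise
    floor.  With ``pac_spec = (lf, hf, depth)`` a channel additionally
    carries a low-frequency rhythm at ``lf`` Hz — a cosine whose phase
    performs a slow random walk (diffusion ``lf_phase_diffusion``), since
    cortical rhythms hold phase only over seconds — and a narrowband noise
    carrier centred at ``hf`` Hz whose amplitude is
    ``(1 + depth·cos(φ_LF(t)))/2``-modulated by the rhythm's phase.
    """
    if duration is None:
        duration = config.duration
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _as_rng(config.rng_seed if seed is None else seed)
    rate = config.lfp_rate
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    chans = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        sig = _one_over_f_noise(
            n, rate, config.one_over_f_exponent, config.background_std, rng,
            highpass=config.lfp_highpass,
        )
        sig = sig + config.sensor_noise_std * rng.standard_normal(n)
        if config.pac_spec is not None:
            lf, hf, depth = config.pac_spec
            drift = np.cumsum(
                np.sqrt(config.lf_phase_diffusion / rate) * rng.standard_normal(n)
            )
            phi_lf = TWO_PI * lf * t + rng.uniform(0, TWO_PI) + drift
            sig = sig + config.lf_osc_amplitude * np.cos(phi_lf)
            env = (1.0 + depth * np.cos(phi_lf)) / 2.0
            carrier = _narrowband_noise(
                n, rate, hf, config.hf_band_sigma, config.hf_carrier_amplitude, rng
            )
            sig = sig + env * carrier
        chans[c] = sig
    return Recording(
        samples=chans,
        rate=rate,
        geometry=config.geometry(),
        pitch=config.pitch,
        band_label="LFP",
    )


def inject_artifact(
    recording: Recording,
    protocol: StimProtocol,
    artifact_gradient: tuple[float, float],
    base_amplitude: float = 500.0,
) -> Recording:
    """Add the stimulation artifact: a sinusoid at the stimulation frequency
    whose per-channel amplitude follows a planar gradient.

    Channel at grid position (row, col) — i.e. physical (x, y) =
    (col·pitch, row·pitch) mm from the array corner — gains amplitude
    ``base_amplitude + 1000·(g_x·x + g_y·y)`` µV, with the gradient in
    mV/mm.  Deterministic; requires geometry.
    """
    if recording.geometry is None:
        raise ValueError("recording must carry array geometry")
    gx, gy = artifact_gradient
    t = recording.times()
    on = (t >= protocol.onset) & (t < protocol.offset)
    x_arg = TWO_PI * protocol.frequency * (t[on] - protocol.onset) + protocol.phase_at_onset
    carrier = np.sin(x_arg)
    out = recording.samples.copy()
    for ch, (row, col) in enumerate(recording.geometry):
        x_mm = col * recording.pitch
        y_mm = row * recording.pitch
        amp = base_amplitude + 1000.0 * (gx * x_mm + gy * y_mm)
        out[ch, on] += amp * carrier
    rec = recording.copy(samples=out)
    return rec


@dataclass
class Session:
    """A generated session: recordings, spike trains, and the ground truth."""

    config: SynthConfig
    protocols: list[StimProtocol]
    lfp: Recording
    mua: Recording | None
    spiketrains: list[SpikeTrain]
    ground_truth: pd.DataFrame  # per neuron
    channel_truth: pd.DataFrame  # per channel

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.lfp.save(outdir / "lfp")
        if self.mua is not None:
            self.mua.save(outdir / "mua")
        spiketrains_to_csv(self.spiketrains, outdir / "spikes.csv")
        self.ground_truth.to_csv(outdir / "ground_truth_neurons.csv", index=False)
        self.channel_truth.to_csv(outdir / "ground_truth_channels.csv", index=False)
        proto = pd.DataFrame(
            [
                {
                    "frequency_hz": p.frequency,
                    "amplitude_ua": p.amplitude,
                    "onset_s": p.onset,
                    "offset_s": p.offset,
                    "sampling_rate_hz": p.sampling_rate,
                    "phase_at_onset_rad": p.phase_at_onset,
                }
                for p in self.protocols
            ],
            columns=[
                "frequency_hz", "amplitude_ua", "onset_s", "offset_s",
                "sampling_rate_hz", "phase_at_onset_rad",
            ],
        )
        proto.to_csv(outdir / "protocols.csv", index=False)


def _spike_waveform(rate: float) -> np.ndarray:
    """1-ms biphasic extracellular spike template (µV), negative-leading."""
    n = max(int(round(1e-3 * rate)), 8)
    tt = np.linspace(0, 1e-3, n, endpoint=False)
    wf = -80.0 * np.exp(-(((tt - 0.25e-3) / 0.12e-3) ** 2)) + 35.0 * np.exp(
        -(((tt - 0.55e-3) / 0.2e-3) ** 2)
    )
    return wf


def gen_session(
    config: SynthConfig,
    protocols: list[StimProtocol],
    seed=None,
    include_mua: bool = False,
) -> Session:
    """Assemble a full synthetic session for one subject.

    Each channel hosts ``n_neurons_per_channel`` neurons with log-normal
    baseline rates (median ``baseline_rate``).  Response classes are drawn
    from the configured fractions, and only the first protocol's window is
    used to modulate spiking when several protocols are supplied (trials are
    separated in time, so each train is modulated by the protocol covering
    it).  The returned ground-truth tables record each neuron's true rate
    change, concentration and preferred phase, and each channel's PAC depth
    and artifact gradient.
    """
    protos = sorted(protocols, key=lambda p: p.onset)
    for a, b in zip(protos, protos[1:]):
        if b.onset < a.offset:
            raise ValueError("protocols overlap in time")
    if protos and protos[-1].offset > config.duration + 1e-9:
        raise ValueError("protocol extends beyond session duration")

    rng = _as_rng(config.rng_seed if seed is None else seed)
    lfp = gen_lfp(config, config.duration, seed=rng)
    for p in protos:
        lfp = inject_artifact(
            lfp, p, config.artifact_gradient, config.artifact_base_amplitude
        )

    n_neurons = config.n_channels * config.n_neurons_per_channel
    classes = np.array(["none"] * n_neurons, dtype=object)
    u = rng.uniform(size=n_neurons)
    fe, fx, fs = config.frac_entrained, config.frac_excited, config.frac_suppressed
    classes[u < fe] = "entrained"
    classes[(u >= fe) & (u < fe + fx)] = "excited"
    classes[(u >= fe + fx) & (u < fe + fx + fs)] = "suppressed"

    base_rates = config.baseline_rate * np.exp(
        config.rate_sigma * rng.standard_normal(n_neurons)
    )

    trains: list[SpikeTrain] = []
    truth_rows = []
    for i in range(n_neurons):
        ch = i // config.n_neurons_per_channel
        cls = classes[i]
        kappa = config.kappa if cls == "entrained" else 0.0
        factor = {
            "excited": config.excite_factor,
            "suppressed": config.suppress_factor,
        }.get(cls, 1.0)
        tr = _gen_multi_protocol_train(
            rate=base_rates[i],
            duration=config.duration,
            kappa=kappa,
            preferred_phase=config.preferred_phase,
            protocols=protos,
            stim_rate_factor=factor,
            rng=rng,
            neuron_id=f"ch{ch:02d}_n{i % config.n_neurons_per_channel}",
            channel_id=ch,
        )
        trains.append(tr)
        truth_rows.append(
            {
                "neuron_id": tr.neuron_id,
                "channel_id": ch,
                "class": cls,
                "baseline_rate_hz": base_rates[i],
                "stim_rate_factor": factor,
                "true_delta_fr_hz": base_rates[i] * (factor - 1.0),
                "kappa": kappa,
                "preferred_phase_rad": config.preferred_phase,
            }
        )

    mua = None
    if include_mua:
        n_mua = int(round(config.duration * config.mua_rate))
        mua_samples = config.mua_noise_std * rng.standard_normal(
            (config.n_channels, n_mua)
        )
        wf = _spike_waveform(config.mua_rate)
        for tr in trains:
            idx = np.round(tr.times * config.mua_rate).astype(int)
            for j in idx:
                stop = min(j + wf.size, n_mua)
                if stop > j >= 0:
                    mua_samples[tr.channel_id, j:stop] += wf[: stop - j]
        mua = Recording(
            samples=mua_samples,
            rate=config.mua_rate,
            geometry=config.geometry(),
            pitch=config.pitch,
            band_label="MUA",
        )
        for p in protos:
            mua = inject_artifact(
                mua, p, config.artifact_gradient, config.artifact_base_amplitude
            )

    depth = config.pac_spec[2] if config.pac_spec is not None else 0.0
    channel_truth = pd.DataFrame(
        {
            "channel_id": np.arange(config.n_channels),
            "row": [g[0] for g in config.geometry()],
            "col": [g[1] for g in config.geometry()],
            "pac_depth": depth,
            "artifact_gx_mv_per_mm": config.artifact_gradient[0],
            "artifact_gy_mv_per_mm": config.artifact_gradient[1],
        }
    )
    return Session(
        config=config,
        protocols=protos,
        lfp=lfp,
        mua=mua,
        spiketrains=trains,
        ground_truth=pd.DataFrame(truth_rows),
        channel_truth=channel_truth,
    )


def _gen_multi_protocol_train(
    rate, duration, kappa, preferred_phase, protocols, stim_rate_factor, rng,
    neuron_id, channel_id,
) -> SpikeTrain:
    """Concatenate per-segment Poisson pieces across several trial windows."""
    if not protocols:
        return gen_spiketrain(
            rate, duration, 0.0, preferred_phase, None, rng,
            neuron_id=neuron_id, channel_id=channel_id,
        )
    pieces = []
    cursor = 0.0
    for p in protocols:
        if p.onset > cursor:
            seg = gen_spiketrain(
                rate, p.onset - cursor, 0.0, preferred_phase, None, rng
            ).times + cursor
            pieces.append(seg)
        shifted = StimProtocol(
            frequency=p.frequency,
            amplitude=p.amplitude,
            onset=0.0,
            offset=p.offset - p.onset,
            sampling_rate=p.sampling_rate,
            phase_at_onset=p.phase_at_onset,
        )
        seg = gen_spiketrain(
            rate,
            p.offset - p.onset,
            kappa,
            preferred_phase,
            shifted,
            rng,
            stim_rate_factor=stim_rate_factor,
        ).times + p.onset
        pieces.append(seg)
        cursor = p.offset
    if duration > cursor:
        seg = gen_spiketrain(
            rate, duration - cursor, 0.0, preferred_phase, None, rng
        ).times + cursor
        pieces.append(seg)
    times = np.unique(np.concatenate(pieces)) if pieces else np.empty(0)
    return SpikeTrain(neuron_id, channel_id, times)
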