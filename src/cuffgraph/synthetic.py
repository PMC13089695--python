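"""Synthetic spatiotemporal signature generator and training augmentation.

Each synthetic signature emulates a compound action potential sweeping
along the cuff: a biphasic pulse appears on every contact with (a) an
amplitude that decays with geodesic distance from a class-specific origin
contact, and (b) an onset delay proportional to the ring offset from the
origin ring, mimicking conduction along the nerve.  Class identity is thus
carried by the circumferential/longitudinal activation pattern — exactly
the spatial prior a geodesic electrode graph encodes.  Subject
heterogeneity enters as a per-subject multiplicative gain and a per-subject
onset jitter; measurement noise is i.i.d. Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LABELS, Signature, SignatureDataset
from .geometry import CuffLayout, geodesic_distance

__all__ = ["SynthConfig", "generate_dataset", "augment_gaussian"]

# fraction of the window before the earliest possible pulse onset
_BASE_ONSET = 20.0


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``n_per_class`` may be one integer (all subjects, all classes), a
    3-sequence (per class, shared across subjects), or a per-subject list
    of 3-sequences to emulate subject-level class imbalance.
    ``class_origins`` gives one (onset ring x0, circumferential center y0)
    per class.  The defaults are chosen so that no cuff-graph automorphism
    (circumferential rotation or reflection, ring-order reversal) maps one
    class's activation template onto another's: classifiers built from
    permutation-equivariant layers plus global pooling are invariant under
    graph automorphisms, so automorphic classes would be provably
    indistinguishable.  Distinct ring offsets |x0 - center| guarantee this
    and also give each class a distinct conduction-delay profile.
    Time-like scales are in samples; gains are dimensionless.
    """

    n_subjects: int = 4
    n_per_class: int | tuple = 40
    seed: int = 0
    n_timesamples: int = 100
    class_origins: tuple[tuple[int, int], ...] = ((0, 0), (2, 3), (5, 6))
    conduction_step: float = 3.0
    pulse_width: float = 4.0
    spatial_sigma: float = 1.5
    subject_gain_sd: float = 0.2
    subject_jitter_sd: float = 2.0
    noise_sd: float = 0.1

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_timesamples < 1:
            raise ValueError("counts must be positive")
        if len(self.class_origins) != len(LABELS):
            raise ValueError(
                f"class_origins must give one origin per class "
                f"({len(LABELS)}), got {len(self.class_origins)}")
        for name in ("conduction_step", "pulse_width", "spatial_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("subject_gain_sd", "subject_jitter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def counts_for(self, subject_index: int) -> list[int]:
        """Per-class sample counts for one subject."""
        npc = self.n_per_class
        if isinstance(npc, int):
            return [npc] * len(LABELS)
        npc = list(npc)
        if npc and isinstance(npc[0], (list, tuple)):
            if len(npc) != self.n_subjects:
                raise ValueError("per-subject counts must match n_subjects")
            per = list(npc[subject_index])
        else:
            per = npc
        if len(per) != len(LABELS):
            raise ValueError("per-class counts must have one entry per class")
        return [int(c) for c in per]


def _class_template(layout: CuffLayout, cfg: SynthConfig, class_idx: int,
                    jitter: float) -> np.ndarray:
    """Noise-free (channels x time) template for one class and onset jitter."""
    x0, y0 = cfg.class_origins[class_idx]
    origin = layout.node(x0 % layout.n_rings, y0 % layout.n_contacts)
    t = np.arange(cfg.n_timesamples, dtype=np.float64)
    out = np.empty((layout.n_nodes, cfg.n_timesamples))
    w = cfg.pulse_width
    for ch in range(layout.n_nodes):
        x, _ = layout.coords(ch)
        d = geodesic_distance(ch, origin, layout)
        amp = np.exp(-(d * d) / (2.0 * cfg.spatial_sigma ** 2))
        onset = _BASE_ONSET + abs(x - x0) * cfg.conduction_step + jitter
        tau = t - onset
        # biphasic pulse: positive lobe then delayed negative lobe
        pulse = (np.exp(-(tau ** 2) / (2.0 * w * w))
                 - np.exp(-((tau - 1.5 * w) ** 2) / (2.0 * w * w)))
        out[ch] = amp * pulse
    return out


def generate_dataset(layout: CuffLayout, cfg: SynthConfig) -> SignatureDataset:
    """Generate a labeled synthetic dataset, reproducible under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    signatures: list[Signature] = []
    for s in range(cfg.n_subjects):
        subject_id = f"S{s + 1:02d}"
        gain = float(np.exp(rng.normal(0.0, cfg.subject_gain_sd))) \
            if cfg.subject_gain_sd > 0 else 1.0
        jitter = float(rng.normal(0.0, cfg.subject_jitter_sd)) \
            if cfg.subject_jitter_sd > 0 else 0.0
        counts = cfg.counts_for(s)
        templates = [gain * _class_template(layout, cfg, c, jitter)
                     for c in range(len(LABELS))]
        for c, label in enumerate(LABELS):
            for _ in range(counts[c]):
                values = templates[c].copy()
                if cfg.noise_sd > 0:
                    values += rng.normal(0.0, cfg.noise_sd, size=values.shape)
                signatures.append(Signature(values=values.astype(np.float32),
                                            label=label, subject_id=subject_id))
    return SignatureDataset(signatures, layout)


def augment_gaussian(sig: Signature, noise_fraction: float, seed: int) -> Signature:
    """Add zero-mean Gaussian noise with sd = noise_fraction x signal RMS.

    Low-amplitude noise injection is the training-time augmentation: it
    perturbs the waveform without moving the spatiotemporal pattern.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be non-negative")
    if noise_fraction == 0:
        return Signature(values=sig.values.copy(), label=sig.label,
                         subject_id=sig.subject_id)
    rms = float(np.sqrt(np.mean(sig.values.astype(np.float64) ** 2)))
    rng = np.random.default_rng(seed)
    noisy = sig.values + rng.normal(0.0, noise_fraction * rms,
                                    size=sig.values.shape).astype(sig.values.dtype)
    return Signature(values=noisy, label=sig.label, subject_id=sig.subject_id)
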