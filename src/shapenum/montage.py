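"""64-channel extended 10-20 montage with unit-sphere positions.

Positions come from the standard 10-05 electrode description shipped with
MNE-Python, projected onto the unit sphere around the head centre. The
recording reference is CZ; a single bipolar VEOG channel models vertical
electro-oculogram pickup for blink simulation and correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# 64 analysis electrodes; includes every location used in the component
# analyses (P7/PO5/PO7 | P8/PO6/PO8 posterior sets and FC1/FC3/C1/C3).
CHANNELS_64 = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2", "Iz",
]

VEOG = "VEOG"


@dataclass
class Montage:
    ch_names: list[str]
    positions: np.ndarray        # (n_channels, 3) unit vectors
    reference: str = "Cz"
    veog: str = VEOG

    def __post_init__(self) -> None:
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def index(self, name: str) -> int:
        lowered = [c.lower() for c in self.ch_names]
        return lowered.index(name.lower())

    def indices(self, names: list[str]) -> list[int]:
        return [self.index(n) for n in names]

    def great_circle_distances(self) -> np.ndarray:
        """Pairwise angular distances (radians) between electrodes."""
        cosang = np.clip(self.positions @ self.positions.T, -1.0, 1.0)
        return np.arccos(cosang)


def make_montage() -> Montage:
    """Build the 64-channel montage from the standard 10-05 positions."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]
    lowered = {k.lower(): v for k, v in pos.items()}
    coords = np.array([lowered[name.lower()] for name in CHANNELS_64])
    centre = coords.mean(axis=0)
    vecs = coords - centre
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    return Montage(list(CHANNELS_64), vecs)


@dataclass
class GroundTruth:
    """Planted simulation truth for one experiment.

    ``templates`` holds average-referenced unit-GFP maps for the three
    evoked generators; ``amplitudes`` maps condition label -> component ->
    signed peak amplitude in microvolts; ``blink_coeffs`` are per-channel
    VEOG propagation factors.
    """

    montage: Montage
    templates: dict[str, np.ndarray]            # component -> (64,)
    amplitudes: dict[str, dict[str, float]]     # label -> component -> uV
    windows: dict[str, tuple[float, float]]     # component -> (ms, ms)
    blink_coeffs: np.ndarray                    # (64,)
    analysis_electrodes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(ANALYSIS_ELECTRODES))
    blink_rate_hz: float = 0.15
    blink_amplitude_uv: float = 250.0
    artifact_rate: float = 0.05
    artifact_amplitude_uv: float = 120.0
    experiment: int = 1
    # topographic plant: shape conditions add this much of the N1-map
    # generator during the N2 window, so configuration differs in map shape
    # (not just strength) there -- the signature TANOVA can detect
    topo_admixture_uv: float = 1.2
    behavior: dict[str, dict[str, float]] = field(default_factory=dict)
    # label -> {"p_correct": .., "rt_median_ms": .., "rt_sigma": .., "rt_shift_ms": ..}

    def to_json(self) -> dict:
        return {
            "templates": {k: v.tolist() for k, v in self.templates.items()},
            "amplitudes": self.amplitudes,
            "windows": {k: list(v) for k, v in self.windows.items()},
            "blink_coeffs": self.blink_coeffs.tolist(),
            "blink_rate_hz": self.blink_rate_hz,
            "blink_amplitude_uv": self.blink_amplitude_uv,
            "artifact_rate": self.artifact_rate,
            "artifact_amplitude_uv": self.artifact_amplitude_uv,
            "behavior": self.behavior,
        }


def _gaussian_patch(montage: Montage, centre_channels: list[str],
                    width_rad: float) -> np.ndarray:
    """Average-referenced, unit-GFP map peaking over the given electrodes."""
    pos = montage.positions
    centre = pos[montage.indices(centre_channels)].mean(axis=0)
    centre /= np.linalg.norm(centre)
    ang = np.arccos(np.clip(pos @ centre, -1, 1))
    m = np.exp(-(ang ** 2) / (2 * width_rad ** 2))
    m -= m.mean()
    gfp = np.sqrt((m ** 2).mean())
    return m / gfp


def make_templates(montage: Montage,
                   specs: dict[str, tuple[list[str], float, float]] | None = None,
                   ) -> dict[str, np.ndarray]:
    """Generator topographies for the three evoked components.

    N1 and N2 are bilateral posterior negativities with slightly different
    centroids/widths (so their maps are distinguishable); the LMF peaks over
    left fronto-central sites. ``specs`` maps component name to
    (centre electrode list, angular width in radians, sign).
    """
    out = {}
    if specs is None:
        # N1: midline occipital negativity; N2: lateral posterior negativity
        # with right-hemisphere dominance (as in the component analyses);
        # LMF: left fronto-central positivity. The N2/LMF pair is kept well
        # below |r| = 0.5 so segmentation can separate the generators.
        n1 = -_gaussian_patch(montage, ["Oz", "O1", "O2", "Iz"], 0.45)
        n2 = -(1.0 * _gaussian_patch(montage, ["P8", "PO8"], 0.5)
               + 0.55 * _gaussian_patch(montage, ["P7", "PO7"], 0.5))
        n2 -= n2.mean()
        n2 /= np.sqrt((n2 ** 2).mean())
        lmf = _gaussian_patch(montage, ["FC1", "FC3", "C1", "C3"], 0.5)
        out = {"N1": n1, "N2": n2, "LMF": lmf}
        return out
    for name, (chans, width, sign) in specs.items():
        out[name] = sign * _gaussian_patch(montage, chans, width)
    return out


DEFAULT_WINDOWS = {"N1": (160.0, 220.0), "N2": (250.0, 400.0),
                   "LMF": (400.0, 650.0)}

# electrode sets of the component mean-amplitude analyses
ANALYSIS_ELECTRODES = {
    "N1": ("P7", "PO5", "PO7", "P8", "PO6", "PO8"),
    "N2": ("P7", "PO5", "PO7", "P8", "PO6", "PO8"),
    "LMF": ("FC1", "FC3", "C1", "C3"),
}


def default_amplitudes(experiment: int) -> dict[str, dict[str, float]]:
    """Planted per-condition component amplitudes (microvolts).

    Encodes the qualitative effect structure: the N2 negativity is larger
    (more negative) for shape than random configurations and for
    different-polarity than same-polarity stimuli; LMF amplitude orders
    3 > 4 > 5 ~ 6 and is untouched by polarity.
    """
    lmf = {3: 3.0, 4: 2.2, 5: 1.5, 6: 1.45}
    table: dict[str, dict[str, float]] = {}
    from .stimuli import conditions_for_experiment

    for cond in conditions_for_experiment(experiment):
        n = cond.n_elements
        if experiment == 3:
            different = cond.polarity_scheme == "mixed"
            n1 = -4.0 - 0.1 * n
            n2 = -3.5 if different else -2.5
            lmf_amp = lmf[n]
        else:
            shape = cond.configuration == "shape"
            n1 = (-4.5 if shape else -4.0) - 0.1 * n
            n2 = (-3.5 if shape else -2.0) - 0.05 * n
            lmf_amp = lmf[n] + (0.4 if shape else 0.0)
        table[cond.label] = {"N1": n1, "N2": n2, "LMF": lmf_amp}
    return table


def default_behavior(experiment: int) -> dict[str, dict[str, float]]:
    """Planted behaviour: accuracy falls and RT rises with numerosity;
    shape (or same-polarity) conditions are faster and more accurate."""
    from .stimuli import conditions_for_experiment

    acc = {3: 0.97, 4: 0.95, 5: 0.86, 6: 0.82}
    rt = {3: 500.0, 4: 515.0, 5: 595.0, 6: 610.0}
    out: dict[str, dict[str, float]] = {}
    for cond in conditions_for_experiment(experiment):
        n = cond.n_elements
        if experiment == 3:
            favoured = cond.polarity_scheme != "mixed"
            dp, drt = (0.014, -7.0) if favoured else (0.0, 0.0)
        else:
            favoured = cond.configuration == "shape"
            dp, drt = (0.03, -40.0) if favoured else (0.0, 0.0)
        out[cond.label] = {
            "p_correct": min(acc[n] + dp, 0.995),
            "rt_median_ms": rt[n] + drt,
            "rt_sigma": 0.22,
            "rt_shift_ms": 180.0,
        }
    return out


def make_ground_truth(experiment: int = 1,
                      montage: Montage | None = None) -> GroundTruth:
    montage = montage or make_montage()
    templates = make_templates(montage)
    # blink propagation decays with angular distance from the frontal pole
    fp = montage.positions[montage.index("Fpz")]
    ang = np.arccos(np.clip(montage.positions @ fp, -1, 1))
    blink = 0.03 + 0.35 * np.exp(-ang / 0.8)
    return GroundTruth(
        montage=montage,
        templates=templates,
        amplitudes=default_amplitudes(experiment),
        windows=dict(DEFAULT_WINDOWS),
        blink_coeffs=blink,
        behavior=default_behavior(experiment),
        experiment=experiment,
        topo_admixture_uv=1.2 if experiment in (1, 2) else 0.0,
    )
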