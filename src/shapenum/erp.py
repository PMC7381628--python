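"""Component mean amplitudes in the canonical windows and electrode sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import SubjectERP


class MissingElectrodeError(KeyError):
    pass


@dataclass(frozen=True)
class ComponentWindow:
    name: str
    t_start_ms: float
    t_end_ms: float
    electrodes: tuple[str, ...]
    hemisphere_split: bool = False

    @property
    def left(self) -> tuple[str, ...]:
        return tuple(e for e in self.electrodes if int(e[-1]) % 2 == 1)

    @property
    def right(self) -> tuple[str, ...]:
        return tuple(e for e in self.electrodes if int(e[-1]) % 2 == 0)


N1_WINDOW = ComponentWindow("N1", 160.0, 220.0,
                            ("P7", "PO5", "PO7", "P8", "PO6", "PO8"), True)
N2_WINDOW = ComponentWindow("N2", 250.0, 400.0,
                            ("P7", "PO5", "PO7", "P8", "PO6", "PO8"), True)
LMF_WINDOW = ComponentWindow("LMF", 400.0, 650.0,
                             ("FC1", "FC3", "C1", "C3"), False)
COMPONENT_WINDOWS = {"N1": N1_WINDOW, "N2": N2_WINDOW, "LMF": LMF_WINDOW}


def mean_amplitude(erp: SubjectERP, window: ComponentWindow) -> pd.DataFrame:
    """Mean amplitude per listed electrode over [t_start, t_end], endpoints
    inclusive. Returns tidy rows (subject, condition, component, electrode,
    amplitude_uv)."""
    sel = (erp.times_ms >= window.t_start_ms) & (erp.times_ms <= window.t_end_ms)
    if not sel.any():
        raise ValueError("window outside the epoch time base")
    rows = []
    for e in window.electrodes:
        try:
            i = [c.lower() for c in erp.ch_names].index(e.lower())
        except ValueError as err:
            raise MissingElectrodeError(e) from err
        rows.append((erp.subject, erp.condition, window.name, e,
                     float(erp.data[i, sel].mean())))
    return pd.DataFrame(rows, columns=["subject", "condition", "component",
                                       "electrode", "amplitude_uv"])


def amplitude_table(erps_by_subject: dict[int, dict[str, SubjectERP]],
                    windows: dict[str, ComponentWindow] | None = None
                    ) -> pd.DataFrame:
    """AmplitudeTable over subjects x conditions x components x electrodes."""
    windows = windows or COMPONENT_WINDOWS
    frames = []
    for erps in erps_by_subject.values():
        for erp in erps.values():
            for w in windows.values():
                frames.append(mean_amplitude(erp, w))
    return pd.concat(frames, ignore_index=True)


def parse_condition_label(label: str) -> tuple[str, int]:
    """Split a condition label such as 'S3' or 'R6' into (group, n)."""
    return label[0], int(label[1:])


def component_cell_means(table: pd.DataFrame, component: str) -> pd.DataFrame:
    """Subject x condition mean amplitude for one component (averaged over
    the electrode set), with the condition factors split out."""
    sub = table[table["component"] == component]
    cell = (sub.groupby(["subject", "condition"])["amplitude_uv"]
            .mean().reset_index())
    parsed = cell["condition"].map(parse_condition_label)
    cell["configuration"] = [p[0] for p in parsed]
    cell["n_elements"] = [p[1] for p in parsed]
    return cell
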