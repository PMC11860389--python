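"""Interpretability artifacts: model cards and posterior-trace plots.

Plots are views: every number they show is recomputable from the serialized
Prediction / ProbabilitySeries JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .classification import CLASS_ORDER, ProbabilitySeries  # noqa: E402
from .hmm_core import HmmModel  # noqa: E402
from .signal_io import AudioSignal  # noqa: E402


class ReportError(ValueError):
    """Raised on inconsistent reporting inputs."""


def model_digest(model: HmmModel) -> str:
    payload = json.dumps(model.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def render_model_card(model: HmmModel, provenance: dict | None = None,
                      expected_digest: str | None = None) -> str:
    """Human-readable Markdown card of a model's internal state.

    Shows the transition table, per-state self-transition probabilities
    (the dwell-time diagnostic: higher values mean the state's speech
    pattern persists longer) and mixture summaries. Missing provenance
    flags the card as unaudited; a digest mismatch is an error.
    """
    digest = model_digest(model)
    if expected_digest is not None and expected_digest != digest:
        raise ReportError(
            f"digest mismatch: expected {expected_digest}, got {digest}")
    lines = [
        "# Model card",
        "",
        f"- digest: `{digest}`",
        f"- states: {model.n_states}, mixtures/state: {model.n_mixtures}, "
        f"topology: {model.topology}",
    ]
    if provenance:
        for key, val in provenance.items():
            lines.append(f"- {key}: {val}")
    else:
        lines.append("- **unaudited**: no provenance supplied")
    lines += ["", "## Transition matrix (rows sum to 1.000)", ""]
    header = "| from\\to | " + " | ".join(
        str(j) for j in range(model.n_states)) + " | row sum |"
    lines += [header, "|" + "---|" * (model.n_states + 2)]
    for i, row in enumerate(model.transitions):
        cells = " | ".join(f"{v:.3f}" for v in row)
        lines.append(f"| {i} | {cells} | {row.sum():.3f} |")
    diag = np.diag(model.transitions)
    lines += ["", "## Self-transition (state persistence) diagnostics", ""]
    for i, v in enumerate(diag):
        lines.append(f"- state {i}: a_ii = {v:.4f}")
    lines += ["", "## State mixtures", ""]
    for s, g in enumerate(model.state_pdfs):
        lines.append(
            f"- state {s}: weights {np.round(g.weights, 3).tolist()}, "
            f"mean norm {np.linalg.norm(g.means, axis=1).round(2).tolist()}")
    return "\n".join(lines) + "\n"


def render_posterior_plot(series: ProbabilitySeries, signal: AudioSignal,
                          out: str | Path, top_segments=None) -> Path:
    """Waveform plus per-class posterior traces (and optional highlights)."""
    if abs(signal.duration - float(series.window_times[-1]
                                   + series.window_s / 2)) > series.window_s:
        raise ReportError("series and signal durations disagree")
    fig, (ax_w, ax_p) = plt.subplots(
        2, 1, sharex=True, figsize=(10, 5),
        gridspec_kw={"height_ratios": [1, 1.4]})
    t = np.arange(signal.samples.size) / signal.rate
    ax_w.plot(t, signal.samples, lw=0.3, color="gray")
    ax_w.set_ylabel("amplitude")
    for j, cls in enumerate(CLASS_ORDER):
        ax_p.plot(series.window_times, series.posteriors[:, j],
                  marker="o", ms=3, label=cls)
    if top_segments:
        for start, end, cls, conf in top_segments:
            ax_p.axvspan(start, end, alpha=0.15, color="tab:red")
    ax_p.axhline(0.5, ls=":", color="k", lw=0.8)
    ax_p.set_ylim(-0.05, 1.05)
    ax_p.set_xlabel("time (s)")
    ax_p.set_ylabel("posterior")
    ax_p.legend(loc="upper right")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=100)
    plt.close(fig)
    return out
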