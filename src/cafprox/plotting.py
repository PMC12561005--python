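"""Optional rendering of radial distance histograms (matplotlib)."""

from __future__ import annotations

from .proximity import RadialProfile


def plot_radial_profile(profile: RadialProfile, ax=None, use_density: bool = False):
    """Bar plot of a radial profile (counts, or density per 100 μm²)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    lo = profile.bin_edges[:-1]
    width = profile.bin_edges[1] - profile.bin_edges[0]
    y = profile.density if (use_density and profile.density is not None) else profile.counts
    ax.bar(lo, y, width=width, align="edge", edgecolor="black", linewidth=0.5)
    ax.set_xlabel(f"distance to nearest {profile.target_type} (μm)")
    ax.set_ylabel("CAF density (per 100 μm²)" if use_density else "CAF count")
    ax.set_xlim(profile.bin_edges[0], profile.bin_edges[-1])
    return ax
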