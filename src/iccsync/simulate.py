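"""Synthetic multi-subject BOLD datasets with known ground truth.

The generator emulates the study conditions the analysis is built for:
an 8-minute resting scan of n = 240 volumes at TR = 2 s, one 4-minute
eyes-closed (EC) block followed by one 4-minute eyes-open (EO) block
(EO onset at volume 121), and M subjects who share network-shaped
transient responses to the two condition onsets.  Each voxel's series is

    X = subject mean offset + subject amplitude * network template
        + AR(1) noise,

so between-subject mean offsets put the data in the Gamma > 0 regime
where the agreement and consistency indices genuinely differ, and the
AR(1) innovations give the temporal dependence the surrogate null and
the stationarity screen are meant to handle.

Three response families mirror the shapes seen after condition onsets:

* ``positive-transient`` — a gamma-like bump after each onset, larger
  and longer after EO than after EC, decaying back to baseline within
  the configured duration (default 60 s);
* ``negative-transient`` — its negation;
* ``limbic-biphasic`` — a slow decline through the EC block, then a
  short dip followed by a sustained rise after EO onset;
* ``null`` — no shared response.

Templates are parameterized difference-of-exponentials shapes rather
than empirically measured curves.  Amplitudes are declared parameters
of the design; the default signal-to-noise ratio is chosen so the
planted networks are comfortably recoverable by the full pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticDesign",
    "response_template",
    "simulate_dataset",
    "simulate_cortisol",
    "ar1_noise",
    "write_dataset",
]

NETWORK_TYPES = ("positive-transient", "negative-transient", "limbic-biphasic", "null")


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one synthetic acquisition.

    Onsets are 1-based volume indices, matching scanner numbering:
    EC starts at volume 1, EO at volume 121.
    """

    n_volumes: int = 240
    tr: float = 2.0
    n_subjects: int = 10
    grid: tuple[int, int, int] = (12, 12, 8)
    ec_onset: int = 1
    eo_onset: int = 121
    #: temporal standard deviation of the shared response template, in
    #: units of the AR(1) noise innovation sd (the shared-signal SNR)
    response_amplitude: float = 0.45
    #: EC-onset bump amplitude relative to the EO-onset bump
    ec_relative_amplitude: float = 0.5
    #: transient duration in seconds (return to ~baseline after an onset)
    transient_duration: float = 60.0
    #: sd of the per-(subject, network) multiplicative amplitude around 1
    subject_amplitude_sd: float = 0.3
    ar1_coef: float = 0.3
    innovation_sd: float = 1.0
    #: sd of the per-(subject, voxel) mean offset; drives Gamma > 0
    subject_offset_sd: float = 0.5
    seed: int = 0
    networks: tuple[str, ...] = (
        "positive-transient",
        "negative-transient",
        "limbic-biphasic",
    )

    def __post_init__(self):
        if not (1 <= self.ec_onset <= self.n_volumes) or not (
            1 <= self.eo_onset <= self.n_volumes
        ):
            raise ValueError("onsets must lie within [1, n_volumes]")
        if not -1 < self.ar1_coef < 1:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        for net in self.networks:
            if net not in NETWORK_TYPES:
                raise ValueError(f"unknown network type {net!r}")


def _bump(t: np.ndarray, duration: float) -> np.ndarray:
    """Gamma-like difference-of-exponentials bump, peak normalized to 1.

    ``t`` is time since onset in seconds (negative = before onset).  The
    decay constant is duration/5, so the bump is within ~1% of baseline
    at ``duration`` seconds post onset.
    """
    tau_d = duration / 5.0
    tau_r = duration / 15.0
    h = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_d) - np.exp(-np.maximum(t, 0) / tau_r), 0.0)
    return h / h.max() if h.max() > 0 else h


def response_template(network_type: str, design: SyntheticDesign) -> np.ndarray:
    """Noise-free shared response series for one network type.

    Every non-null template is scaled to temporal standard deviation
    ``design.response_amplitude``, so the shared-signal power is
    comparable across response shapes and the amplitude parameter reads
    directly as a signal-to-noise ratio against unit-sd innovations.
    """
    if network_type not in NETWORK_TYPES:
        raise ValueError(f"unknown network type {network_type!r}")
    n, tr = design.n_volumes, design.tr
    t = np.arange(n) * tr  # seconds from scan start (volume 1 at t=0)
    amp = 1.0
    if network_type == "null":
        return np.zeros(n)
    t_ec = t - (design.ec_onset - 1) * tr
    t_eo = t - (design.eo_onset - 1) * tr
    if network_type in ("positive-transient", "negative-transient"):
        shape = amp * (
            design.ec_relative_amplitude * _bump(t_ec, design.transient_duration)
            + _bump(t_eo, design.transient_duration)
        )
        if network_type == "negative-transient":
            shape = -shape
        return design.response_amplitude * shape / shape.std()
    # limbic-biphasic: slow EC decline, short post-EO dip, sustained rise
    ec_len = (design.eo_onset - design.ec_onset) * tr
    out = np.zeros(n)
    in_ec = (t_ec >= 0) & (t_eo < 0)
    out[in_ec] = -amp * (t_ec[in_ec] / ec_len)
    post = t_eo >= 0
    tp = t_eo[post]
    dip = -0.4 * amp * _bump(tp, 20.0)
    rise = -amp + 2.0 * amp * (1.0 - np.exp(-tp / 40.0))
    out[post] = rise + dip
    return design.response_amplitude * out / out.std()


def ar1_noise(
    shape: tuple[int, ...], n: int, coef: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise, time on the last axis: (*shape, n)."""
    eps = rng.normal(0.0, sd, size=shape + (n,))
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0] / np.sqrt(1.0 - coef**2)
    for k in range(1, n):
        out[..., k] = coef * out[..., k - 1] + eps[..., k]
    return out


def _default_atlas(grid: tuple[int, int, int], networks: tuple[str, ...]):
    """Block atlas over the grid with left/right network ROIs.

    The grid is cut into equal blocks (4 voxels a side where possible);
    x-blocks at the low end are "L", at the high end "R", the middle
    slab (if any) is unlabeled midline and left as null ROIs.  Each
    network gets an equal share of the lateral ROIs, alternating L/R so
    every network is bilateral.
    """
    gx, gy, gz = grid
    bs = max(1, min(4, gx // 3, gy // 3, gz // 2))
    nbx, nby, nbz = gx // bs, gy // bs, gz // bs
    atlas = np.zeros(grid, dtype=np.int32)
    rows = []
    roi_id = 0
    lateral: list[int] = []
    for bx in range(nbx):
        hemi = "L" if bx < nbx // 2 else ("R" if bx >= (nbx + 1) // 2 else "")
        for by in range(nby):
            for bz in range(nbz):
                roi_id += 1
                atlas[
                    bx * bs : (bx + 1) * bs,
                    by * bs : (by + 1) * bs,
                    bz * bs : (bz + 1) * bs,
                ] = roi_id
                rows.append(
                    {"label_id": roi_id, "roi_name": f"roi{roi_id:02d}", "hemisphere": hemi,
                     "network_hint": "null"}
                )
                if hemi:
                    lateral.append(roi_id)
    table = pd.DataFrame(rows).set_index("label_id", drop=False)
    n_net = len(networks)
    per = len(lateral) // n_net if n_net else 0
    if per == 0 and n_net:
        raise ValueError("grid too small to host the requested networks")
    # alternate L/R assignment so each network is bilateral
    left = [r for r in lateral if table.loc[r, "hemisphere"] == "L"]
    right = [r for r in lateral if table.loc[r, "hemisphere"] == "R"]
    interleaved = [v for pair in zip(left, right) for v in pair]
    interleaved += left[len(right):] + right[len(left):]
    for j, net in enumerate(networks):
        for r in interleaved[j * per : (j + 1) * per]:
            table.loc[r, "network_hint"] = net
    return atlas, table


def simulate_dataset(
    design: SyntheticDesign, rng: np.random.Generator | int | None = None
) -> dict:
    """Generate per-subject 4-D volumes, atlas, and truth tables.

    Returns a dict with:

    ``data``
        (M, x, y, z, n) float array of BOLD series.
    ``atlas``
        (x, y, z) int32 ROI labels (0 = background; here all in-mask).
    ``mask``
        (x, y, z) boolean brain mask (all True on the synthetic grid).
    ``roi_table``
        DataFrame: label_id, roi_name, hemisphere, network_hint.
    ``truth``
        DataFrame per voxel: flat index, roi label, network type.
    ``subject_amplitudes``
        (M, n_networks) per-subject template multipliers.
    ``design``
        the input design (round-trips via JSON in ``write_dataset``).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(design.seed if rng is None else rng)
    M, n = design.n_subjects, design.n_volumes
    atlas, roi_table = _default_atlas(design.grid, design.networks)
    templates = {net: response_template(net, design) for net in design.networks}

    net_of_roi = roi_table["network_hint"].to_dict()
    voxel_net = np.full(atlas.size, "null", dtype=object)
    flat_atlas = atlas.ravel()
    for roi, net in net_of_roi.items():
        voxel_net[flat_atlas == roi] = net

    amps = 1.0 + rng.normal(0.0, design.subject_amplitude_sd, size=(M, len(design.networks)))
    offsets = rng.normal(0.0, design.subject_offset_sd, size=(M, atlas.size))

    signal = np.zeros((M, atlas.size, n))
    for j, net in enumerate(design.networks):
        sel = voxel_net == net
        if not sel.any():
            continue
        # (M, 1, n) amplitude-scaled template broadcast over member voxels
        signal[:, sel, :] = (amps[:, j, None] * templates[net][None, :])[:, None, :]
    noise = ar1_noise((M, atlas.size), n, design.ar1_coef, design.innovation_sd, rng)
    data = offsets[..., None] + signal + noise
    data = data.reshape((M,) + design.grid + (n,))

    truth = pd.DataFrame(
        {
            "voxel": np.arange(atlas.size),
            "label_id": flat_atlas,
            "network": voxel_net,
        }
    )
    return {
        "data": data,
        "atlas": atlas,
        "mask": np.ones(design.grid, dtype=bool),
        "roi_table": roi_table,
        "truth": truth,
        "subject_amplitudes": amps,
        "design": design,
    }


def simulate_cortisol(
    design: SyntheticDesign,
    connectivity_summary: np.ndarray,
    rng: np.random.Generator | int | None = None,
    target_partial_r: float = 0.5,
    pre_post_corr: float = 0.417,
) -> pd.DataFrame:
    """Subjects table with cortisol tied to a connectivity summary.

    ``connectivity_summary`` is one value per subject (e.g. a
    hemispheric mean of standardized Fisher Z values).  Demographics are
    drawn with moments typical of a young healthy cohort; pre-scan
    cortisol is a linear function of the covariates plus the summary
    plus noise, with the noise scaled so the population partial
    correlation between pre-cortisol and the summary given the
    covariates equals ``target_partial_r``.  Post-scan cortisol is
    correlated with pre-scan cortisol at ``pre_post_corr``.
    """
    if not -1 < target_partial_r < 1:
        raise ValueError("target partial correlation must lie in (-1, 1)")
    s = np.asarray(connectivity_summary, dtype=float).ravel()
    N = s.size
    if N < 8:
        raise ValueError(f"need at least 8 subjects, got {N}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(design.seed if rng is None else rng)
    age = rng.normal(23.4, 2.5, N)
    sex = rng.integers(0, 2, N).astype(float)
    stai_state = np.round(rng.normal(35.3, 11.4, N)).clip(20, 80)
    stai_trait = np.round(rng.normal(41.5, 8.2, N)).clip(20, 80)
    sq_isma = np.round(rng.normal(9.9, 3.8, N)).clip(0, 25)

    sd_s = s.std()
    if sd_s == 0:
        raise ValueError("connectivity summary is constant")
    if target_partial_r == 0:
        beta, sigma_e = 0.0, sd_s
    else:
        beta = 1.0
        sigma_e = sd_s * np.sqrt(1.0 / target_partial_r**2 - 1.0)
    latent = beta * (s - s.mean()) + rng.normal(0.0, sigma_e, N)
    # covariate loadings + scaling into a plausible pg/ml range
    scale = 1200.0 / sd_s
    pre = (
        3600.0
        + 40.0 * (age - age.mean())
        + 500.0 * (sex - sex.mean())
        + 25.0 * (stai_trait - stai_trait.mean())
        + 50.0 * (sq_isma - sq_isma.mean())
        + scale * latent
    )
    pre_c = pre - pre.mean()
    post = (
        5200.0
        + pre_post_corr * pre_c
        + np.sqrt(1.0 - pre_post_corr**2) * rng.normal(0.0, pre_c.std(), N)
    )
    return pd.DataFrame(
        {
            "subject_id": [f"sub{i:03d}" for i in range(N)],
            "age": np.round(age, 1),
            "sex": sex.astype(int),
            "STAI_state": stai_state.astype(int),
            "STAI_trait": stai_trait.astype(int),
            "SQ_ISMA": sq_isma.astype(int),
            "pre_cortisol": np.round(pre, 2),
            "post_cortisol": np.round(post, 2),
        }
    )


def write_dataset(out_dir: str | Path, dataset: dict) -> None:
    """Write a simulated dataset to disk as NIfTI + TSV + JSON."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design: SyntheticDesign = dataset["design"]
    affine = np.diag([3.0, 3.0, 3.74, 1.0])
    for i in range(design.n_subjects):
        img = nib.Nifti1Image(dataset["data"][i].astype(np.float32), affine)
        img.header.set_zooms((3.0, 3.0, 3.74, design.tr))
        nib.save(img, out / f"sub{i:03d}_bold.nii")
    nib.save(nib.Nifti1Image(dataset["atlas"].astype(np.int32), affine), out / "atlas.nii")
    nib.save(
        nib.Nifti1Image(dataset["mask"].astype(np.uint8), affine), out / "mask.nii"
    )
    dataset["roi_table"].to_csv(out / "atlas_labels.tsv", sep="\t", index=False)
    dataset["truth"].to_csv(out / "truth.tsv", sep="\t", index=False)
    np.savetxt(out / "subject_amplitudes.tsv", dataset["subject_amplitudes"], delimiter="\t")
    (out / "design.json").write_text(json.dumps(asdict(design), indent=2, default=list))
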