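"""Synthetic data with recorded ground truth.

Every generator here produces one of the input types consumed downstream —
punctate images, two-channel colocalization pairs, particle trajectories,
label-free quantification (LFQ) matrices, and pairwise sequence-hit tables —
together with a :class:`GroundTruth` record of the true labels (spot
positions, shared flags, track identities and motion classes, enrichment
flags, planted ortholog pairs). All randomness flows from the explicit
``seed`` argument of each call; there is no global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from satquant.core import InvalidParameterError, PixelImage

MOTION_MODES = ("normal", "subdiffusive", "confined", "directed")

#: Columns of the tracker-export spot table dialect.
SPOT_COLUMNS = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y", "INTENSITY", "DIAMETER"]


@dataclass
class GroundTruth:
    """Generator settings plus per-entity true labels.

    ``kind`` names the generated data type; ``parameters`` holds every
    generator argument (so a run can be reproduced); ``records`` is a
    DataFrame with one row per generated entity (spot, track point, protein,
    ortholog pair).
    """

    kind: str
    parameters: dict
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "parameters": self.parameters,
                "records": self.records.to_dict(orient="list"),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(obj["kind"], obj["parameters"], pd.DataFrame(obj["records"]))


def _render_spots(shape, pixel_size_um, positions, amplitudes, sigma_um):
    """Sum of 2D Gaussian kernels evaluated at pixel centres."""
    img = np.zeros(shape, dtype=float)
    sigma_px = sigma_um / pixel_size_um
    half = max(1, int(math.ceil(4 * sigma_px)))
    rows, cols = shape
    for (x, y), amp in zip(positions, amplitudes):
        cx = x / pixel_size_um - 0.5  # pixel-index coordinates of the centre
        cy = y / pixel_size_um - 0.5
        j0, j1 = max(0, int(cx) - half), min(cols, int(cx) + half + 2)
        i0, i1 = max(0, int(cy) - half), min(rows, int(cy) + half + 2)
        if j0 >= j1 or i0 >= i1:
            continue
        jj = np.arange(j0, j1)
        ii = np.arange(i0, i1)
        gx = np.exp(-((jj - cx) ** 2) / (2 * sigma_px**2))
        gy = np.exp(-((ii - cy) ** 2) / (2 * sigma_px**2))
        img[i0:i1, j0:j1] += amp * np.outer(gy, gx)
    return img


def _uniform_positions(rng, n, size_um):
    w, h = size_um
    return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])


def _radial_positions(rng, n, centers_um, decay_um, size_um):
    """Positions with spatial density ∝ exp(−r/decay) around random centers.

    Density is per unit area, so the radius is drawn from Gamma(2, decay)
    (p(r) ∝ r · exp(−r/decay)) with a uniform angle. Rejection-sampled
    against the image bounds so all spots land inside.
    """
    centers = np.atleast_2d(np.asarray(centers_um, dtype=float))
    w, h = size_um
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = n - filled
        c = centers[rng.integers(0, len(centers), m)]
        r = rng.gamma(2.0, decay_um, m)
        theta = rng.uniform(0, 2 * np.pi, m)
        pos = c + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        ok = (pos[:, 0] >= 0) & (pos[:, 0] < w) & (pos[:, 1] >= 0) & (pos[:, 1] < h)
        k = int(ok.sum())
        out[filled:filled + k] = pos[ok]
        filled += k
    return out


def make_puncta_image(
    n_foci: int,
    psf_sigma_um: float = 0.15,
    image_size_um: tuple[float, float] = (20.0, 20.0),
    pixel_size_um: float = 0.1,
    centers_um=None,
    radial_enrichment_um: float | None = None,
    noise_sd: float = 1.0,
    amplitude: float = 100.0,
    seed: int = 0,
) -> tuple[PixelImage, GroundTruth]:
    """Render an image of Gaussian puncta with an optional radial bias.

    When ``radial_enrichment_um`` is given, spot positions are drawn with
    density proportional to ``exp(-r / radial_enrichment_um)`` around the
    supplied ``centers_um`` (emulating centrosome-proximal enrichment);
    otherwise positions are uniform over the field. Per-spot amplitudes vary
    uniformly within ±50% of ``amplitude``. Gaussian read noise of standard
    deviation ``noise_sd`` is added everywhere.
    """
    if n_foci < 0:
        raise InvalidParameterError("n_foci must be >= 0")
    if psf_sigma_um <= 0 or pixel_size_um <= 0:
        raise InvalidParameterError("psf_sigma_um and pixel_size_um must be > 0")
    if image_size_um[0] <= 0 or image_size_um[1] <= 0:
        raise InvalidParameterError("image_size_um must be positive")
    if radial_enrichment_um is not None:
        if radial_enrichment_um <= 0:
            raise InvalidParameterError("radial_enrichment_um must be > 0")
        if centers_um is None or len(np.atleast_2d(centers_um)) == 0:
            raise InvalidParameterError("radial enrichment requires centers_um")

    rng = np.random.default_rng(seed)
    shape = (
        int(round(image_size_um[1] / pixel_size_um)),
        int(round(image_size_um[0] / pixel_size_um)),
    )
    if radial_enrichment_um is not None:
        positions = _radial_positions(rng, n_foci, centers_um, radial_enrichment_um, image_size_um)
    else:
        positions = _uniform_positions(rng, n_foci, image_size_um)
    amplitudes = amplitude * rng.uniform(0.5, 1.5, n_foci)
    img = _render_spots(shape, pixel_size_um, positions, amplitudes, psf_sigma_um)
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, shape)

    truth = GroundTruth(
        kind="image",
        parameters={
            "n_foci": n_foci, "psf_sigma_um": psf_sigma_um,
            "image_size_um": list(image_size_um), "pixel_size_um": pixel_size_um,
            "radial_enrichment_um": radial_enrichment_um, "noise_sd": noise_sd,
            "amplitude": amplitude, "seed": seed,
            "centers_um": None if centers_um is None
            else np.atleast_2d(centers_um).tolist(),
        },
        records=pd.DataFrame({
            "x_um": positions[:, 0], "y_um": positions[:, 1],
            "amplitude": amplitudes,
        }),
    )
    return PixelImage(img, pixel_size_um, "synthetic"), truth


def make_coloc_pair(
    n_foci: int,
    shared_fraction: float,
    jitter_um: float = 0.0,
    psf_sigma_um: float = 0.15,
    image_size_um: tuple[float, float] = (20.0, 20.0),
    pixel_size_um: float = 0.1,
    noise_sd: float = 1.0,
    amplitude: float = 100.0,
    seed: int = 0,
) -> tuple[tuple[PixelImage, PixelImage], GroundTruth]:
    """Two-channel punctate pair with a controlled shared-foci fraction.

    Exactly ``floor(n_foci * shared_fraction)`` channel-B spots are placed at
    channel-A positions plus isotropic Gaussian jitter of SD ``jitter_um``;
    the remaining B spots are independent uniform draws. Amplitudes are drawn
    independently per channel.
    """
    if not 0 <= shared_fraction <= 1:
        raise InvalidParameterError("shared_fraction must be in [0, 1]")
    if n_foci < 0:
        raise InvalidParameterError("n_foci must be >= 0")

    rng = np.random.default_rng(seed)
    shape = (
        int(round(image_size_um[1] / pixel_size_um)),
        int(round(image_size_um[0] / pixel_size_um)),
    )
    pos_a = _uniform_positions(rng, n_foci, image_size_um)
    n_shared = int(math.floor(n_foci * shared_fraction))
    pos_b = np.empty_like(pos_a)
    pos_b[:n_shared] = pos_a[:n_shared]
    if jitter_um > 0 and n_shared:
        pos_b[:n_shared] += rng.normal(0, jitter_um, (n_shared, 2))
    pos_b[n_shared:] = _uniform_positions(rng, n_foci - n_shared, image_size_um)

    amp_a = amplitude * rng.uniform(0.5, 1.5, n_foci)
    amp_b = amplitude * rng.uniform(0.5, 1.5, n_foci)
    img_a = _render_spots(shape, pixel_size_um, pos_a, amp_a, psf_sigma_um)
    img_b = _render_spots(shape, pixel_size_um, pos_b, amp_b, psf_sigma_um)
    if noise_sd > 0:
        img_a = img_a + rng.normal(0, noise_sd, shape)
        img_b = img_b + rng.normal(0, noise_sd, shape)

    truth = GroundTruth(
        kind="coloc_pair",
        parameters={
            "n_foci": n_foci, "shared_fraction": shared_fraction,
            "jitter_um": jitter_um, "psf_sigma_um": psf_sigma_um,
            "image_size_um": list(image_size_um), "pixel_size_um": pixel_size_um,
            "noise_sd": noise_sd, "amplitude": amplitude, "seed": seed,
            "n_shared": n_shared,
        },
        records=pd.DataFrame({
            "a_x_um": pos_a[:, 0], "a_y_um": pos_a[:, 1],
            "b_x_um": pos_b[:, 0], "b_y_um": pos_b[:, 1],
            "shared": np.arange(n_foci) < n_shared,
        }),
    )
    ch_a = PixelImage(img_a, pixel_size_um, "channel_a")
    ch_b = PixelImage(img_b, pixel_size_um, "channel_b")
    return (ch_a, ch_b), truth


def _fgn_increments(rng, n_steps, hurst, dt_s, D, size):
    """Fractional Gaussian noise via Cholesky of the increment covariance.

    Scaled so the per-axis MSD at lag t is ``2 * D * t**(2 * hurst)``.
    """
    k = np.arange(n_steps)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    cov = gamma[np.abs(k[:, None] - k[None, :])]
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_steps))
    z = rng.standard_normal((n_steps,) + tuple(size))
    scale = math.sqrt(2 * D * dt_s ** (2 * hurst))
    return scale * np.einsum("ij,j...->i...", chol, z)


def _reflect_into_disc(pos, center, L):
    """Radially reflect a point into the disc |p - center| <= L."""
    v = pos - center
    r = float(np.hypot(*v))
    while r > L:
        r_new = 2 * L - r
        if r_new < 0:
            r_new = -r_new % (2 * L)
            if r_new > L:
                r_new = 2 * L - r_new
        pos = center + v / r * r_new
        v = pos - center
        r = abs(r_new)
    return pos


def make_tracks(
    mode: str,
    n_tracks: int = 50,
    n_frames: int = 50,
    dt_s: float = 5.0,
    D_um2_s: float | None = None,
    v_um_s: float | None = None,
    alpha: float | None = None,
    L_um: float | None = None,
    loc_noise_um: float = 0.0,
    start_box_um: tuple[float, float] = (30.0, 30.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate 2D particle trajectories and emit per-frame spot detections.

    Modes
    -----
    ``normal``
        Brownian motion: per-axis Gaussian steps of variance ``2*D*dt``.
    ``subdiffusive``
        Fractional Brownian motion with Hurst exponent ``alpha / 2`` so the
        ensemble MSD grows as ``4*D*t**alpha``.
    ``confined``
        Brownian motion reflected at the boundary of a disc of radius
        ``L_um`` centred on the start position.
    ``directed``
        Brownian motion plus constant drift of speed ``v_um_s`` in a random
        per-track direction.

    Returns a spot table in the tracker-export dialect (``TRACK_ID`` left
    empty — linking is the job of :mod:`satquant.tracking`) and ground truth
    holding the true track identity of every detection.
    """
    if mode not in MOTION_MODES:
        raise InvalidParameterError(f"mode must be one of {MOTION_MODES}")
    if dt_s <= 0:
        raise InvalidParameterError("dt_s must be > 0")
    if D_um2_s is None:
        raise InvalidParameterError("D_um2_s is required for every mode")
    if mode == "subdiffusive" and alpha is None:
        raise InvalidParameterError("subdiffusive mode requires alpha")
    if mode == "confined" and L_um is None:
        raise InvalidParameterError("confined mode requires L_um")
    if mode == "directed" and v_um_s is None:
        raise InvalidParameterError("directed mode requires v_um_s")

    rng = np.random.default_rng(seed)
    n_steps = n_frames - 1
    starts = np.column_stack([
        rng.uniform(0, start_box_um[0], n_tracks),
        rng.uniform(0, start_box_um[1], n_tracks),
    ])
    step_sd = math.sqrt(2 * D_um2_s * dt_s)
    drift_theta = rng.uniform(0, 2 * np.pi, n_tracks)

    paths = np.empty((n_tracks, n_frames, 2))
    paths[:, 0] = starts
    if mode == "subdiffusive":
        incs = _fgn_increments(rng, n_steps, alpha / 2.0, dt_s, D_um2_s, (n_tracks, 2))
        paths[:, 1:] = starts[:, None, :] + np.cumsum(np.moveaxis(incs, 0, 1), axis=1)
    elif mode == "confined":
        steps = rng.normal(0, step_sd, (n_tracks, n_steps, 2))
        for t in range(n_tracks):
            p = starts[t].copy()
            for s in range(n_steps):
                p = _reflect_into_disc(p + steps[t, s], starts[t], L_um)
                paths[t, s + 1] = p
    else:
        steps = rng.normal(0, step_sd, (n_tracks, n_steps, 2))
        if mode == "directed":
            drift = v_um_s * dt_s * np.column_stack(
                [np.cos(drift_theta), np.sin(drift_theta)]
            )
            steps = steps + drift[:, None, :]
        paths[:, 1:] = starts[:, None, :] + np.cumsum(steps, axis=1)

    observed = paths.copy()
    if loc_noise_um > 0:
        observed += rng.normal(0, loc_noise_um, observed.shape)

    track_ids = np.repeat(np.arange(n_tracks), n_frames)
    frames = np.tile(np.arange(n_frames), n_tracks)
    flat = observed.reshape(-1, 2)
    spots = pd.DataFrame({
        "TRACK_ID": np.full(len(flat), np.nan),
        "FRAME": frames,
        "POSITION_X": flat[:, 0],
        "POSITION_Y": flat[:, 1],
        "INTENSITY": np.full(len(flat), 100.0),
        "DIAMETER": np.full(len(flat), 0.3),
    })
    truth = GroundTruth(
        kind="tracks",
        parameters={
            "mode": mode, "n_tracks": n_tracks, "n_frames": n_frames,
            "dt_s": dt_s, "D_um2_s": D_um2_s, "v_um_s": v_um_s,
            "alpha": alpha, "L_um": L_um, "loc_noise_um": loc_noise_um,
            "start_box_um": list(start_box_um), "seed": seed,
        },
        records=pd.DataFrame({
            "track_id": track_ids,
            "frame": frames,
            "x_um": flat[:, 0],
            "y_um": flat[:, 1],
            "mode": mode,
        }),
    )
    return spots, truth


def truth_trajectories(truth: GroundTruth, dt_s: float | None = None) -> list:
    """Build :class:`satquant.tracking.Trajectory` objects from track truth.

    Bypasses linking: uses the generator's true track identities. Handy for
    testing the downstream MSD/classification stages in isolation.
    """
    from satquant.tracking import Trajectory

    if truth.kind != "tracks":
        raise InvalidParameterError("truth record is not from make_tracks")
    if dt_s is None:
        dt_s = float(truth.parameters["dt_s"])
    out = []
    for tid, grp in truth.records.groupby("track_id"):
        out.append(Trajectory(int(tid), grp["frame"].to_numpy(),
                              grp[["x_um", "y_um"]].to_numpy(), dt_s=dt_s))
    return out


def make_lfq(
    n_proteins: int = 2000,
    n_samples_per_group: int = 3,
    n_enriched: int = 50,
    effect_log2: float = 2.0,
    sd_log2: float = 0.5,
    missing_rate: float = 0.0,
    censor_strength: float = 3.0,
    contaminant_rate: float = 0.0,
    baseline_mean_log2: float = 25.0,
    baseline_sd_log2: float = 2.0,
    seed: int = 0,
):
    """Simulate a protein × sample log2-LFQ matrix with known enrichment.

    Each protein has a latent baseline log2 abundance drawn from
    Normal(``baseline_mean_log2``, ``baseline_sd_log2``); replicate values
    scatter around it with SD ``sd_log2``. The first ``n_enriched``
    non-contaminant proteins carry an extra ``effect_log2`` in the bait
    group. Missingness is left-censored: the probability that an entry is
    missing follows a logistic curve decreasing in intensity with slope
    ``censor_strength`` per log2 unit, with the curve midpoint calibrated by
    bisection so the expected overall missing fraction equals
    ``missing_rate`` (``censor_strength = 0`` degenerates to uniform
    missingness). Peptide counts and contaminant flags are attached so the
    downstream filters have something to act on.

    Returns ``(matrix, groups, meta, truth)`` where ``matrix`` is a protein ×
    sample DataFrame with NaN for missing entries, ``groups`` maps sample
    names to ``bait``/``control``, and ``meta`` holds Gene/Peptides/
    Contaminant columns.
    """
    if n_enriched > n_proteins:
        raise InvalidParameterError("n_enriched must be <= n_proteins")
    for name, rate in [("missing_rate", missing_rate),
                       ("contaminant_rate", contaminant_rate)]:
        if not 0 <= rate <= 1:
            raise InvalidParameterError(f"{name} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n_samples = 2 * n_samples_per_group
    samples = [f"bait_{i+1}" for i in range(n_samples_per_group)] + \
              [f"control_{i+1}" for i in range(n_samples_per_group)]
    groups = {s: ("bait" if s.startswith("bait") else "control") for s in samples}

    baseline = rng.normal(baseline_mean_log2, baseline_sd_log2, n_proteins)
    values = baseline[:, None] + rng.normal(0, sd_log2, (n_proteins, n_samples))
    enriched = np.zeros(n_proteins, dtype=bool)
    enriched[:n_enriched] = True
    values[enriched, :n_samples_per_group] += effect_log2

    contaminant = np.zeros(n_proteins, dtype=bool)
    if contaminant_rate > 0:
        # contaminants are drawn from the non-enriched pool
        pool = np.where(~enriched)[0]
        n_cont = int(round(contaminant_rate * n_proteins))
        contaminant[rng.choice(pool, size=min(n_cont, len(pool)), replace=False)] = True

    peptides = 1 + rng.poisson(3.0, n_proteins)

    missing = np.zeros_like(values, dtype=bool)
    if missing_rate > 0:
        if censor_strength == 0:
            missing = rng.uniform(size=values.shape) < missing_rate
        else:
            flat = values.ravel()

            def mean_p(c):
                return float(np.mean(expit(-censor_strength * (flat - c))))

            lo, hi = flat.min() - 50, flat.max() + 50
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if mean_p(mid) < missing_rate:
                    lo = mid
                else:
                    hi = mid
            p_miss = expit(-censor_strength * (values - 0.5 * (lo + hi)))
            missing = rng.uniform(size=values.shape) < p_miss

    observed = values.copy()
    observed[missing] = np.nan

    protein_ids = pd.Index([f"P{i:05d}" for i in range(n_proteins)],
                           name="ProteinID")
    matrix = pd.DataFrame(observed, index=protein_ids, columns=samples)
    meta = pd.DataFrame({
        "Gene": [f"gene{i}" for i in range(n_proteins)],
        "Peptides": peptides,
        "Contaminant": contaminant,
    }, index=protein_ids)

    censored = pd.DataFrame({
        "protein_id": np.repeat(protein_ids, n_samples)[missing.ravel()],
        "sample": np.tile(samples, n_proteins)[missing.ravel()],
        "true_value": values[missing],
    })
    truth = GroundTruth(
        kind="lfq",
        parameters={
            "n_proteins": n_proteins, "n_samples_per_group": n_samples_per_group,
            "n_enriched": n_enriched, "effect_log2": effect_log2,
            "sd_log2": sd_log2, "missing_rate": missing_rate,
            "censor_strength": censor_strength,
            "contaminant_rate": contaminant_rate, "seed": seed,
        },
        records=pd.DataFrame({
            "protein_id": protein_ids,
            "enriched": enriched,
            "contaminant": contaminant,
            "baseline_log2": baseline,
        }),
    )
    truth.censored_values = censored  # retained vs deleted comparison
    return matrix, groups, meta, truth


HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _hit_rows(rng, pairs, evalues):
    n = len(pairs)
    lengths = rng.integers(80, 600, n)
    return pd.DataFrame({
        "qseqid": [p[0] for p in pairs],
        "sseqid": [p[1] for p in pairs],
        "pident": rng.uniform(25, 95, n).round(2),
        "length": lengths,
        "mismatch": rng.integers(0, 100, n),
        "gapopen": rng.integers(0, 10, n),
        "qstart": np.ones(n, dtype=int),
        "qend": lengths,
        "sstart": np.ones(n, dtype=int),
        "send": lengths,
        "evalue": evalues,
        "bitscore": np.maximum(20.0, -10 * np.log10(np.maximum(evalues, 1e-180)) + 30),
    })


def make_hits(
    n_a: int = 100,
    n_b: int = 100,
    ortholog_fraction: float = 0.5,
    evalue_range: tuple[float, float] = (1e-30, 1e-5),
    decoy_hits_per_gene: int = 2,
    decoy_evalue_range: tuple[float, float] = (0.5, 10.0),
    seed: int = 0,
):
    """Simulate forward/reverse sequence-hit tables with planted orthologs.

    ``floor(n_a * ortholog_fraction)`` gene pairs are planted as mutual best
    hits with E-values log-uniform in ``evalue_range``. Every gene
    additionally receives ``decoy_hits_per_gene`` hits to random partners
    with E-values in ``decoy_evalue_range`` (above the conventional 0.1
    cutoff), so decoys never displace a planted pair under thresholded
    reciprocal-best-hit analysis.

    Returns ``(forward, reverse, truth)`` — two 12-column hit tables and the
    planted pair list.
    """
    if n_a <= 0 or n_b <= 0:
        raise InvalidParameterError("gene counts must be > 0")
    if not 0 <= ortholog_fraction <= 1:
        raise InvalidParameterError("ortholog_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    a_ids = [f"A{i:04d}" for i in range(n_a)]
    b_ids = [f"B{i:04d}" for i in range(n_b)]
    n_orth = min(int(math.floor(n_a * ortholog_fraction)), n_b)

    b_partners = rng.permutation(n_b)[:n_orth]
    pairs = [(a_ids[i], b_ids[b_partners[i]]) for i in range(n_orth)]
    lo, hi = np.log10(evalue_range[0]), np.log10(evalue_range[1])
    e_orth = 10 ** rng.uniform(lo, hi, n_orth)

    fwd_parts = [_hit_rows(rng, pairs, e_orth)]
    rev_parts = [_hit_rows(rng, [(b, a) for a, b in pairs], e_orth)]

    dlo, dhi = np.log10(decoy_evalue_range[0]), np.log10(decoy_evalue_range[1])
    if decoy_hits_per_gene > 0:
        fa = [(a, b_ids[j]) for a in a_ids
              for j in rng.integers(0, n_b, decoy_hits_per_gene)]
        fb = [(b, a_ids[j]) for b in b_ids
              for j in rng.integers(0, n_a, decoy_hits_per_gene)]
        fwd_parts.append(_hit_rows(rng, fa, 10 ** rng.uniform(dlo, dhi, len(fa))))
        rev_parts.append(_hit_rows(rng, fb, 10 ** rng.uniform(dlo, dhi, len(fb))))

    forward = pd.concat(fwd_parts, ignore_index=True)
    reverse = pd.concat(rev_parts, ignore_index=True)
    truth = GroundTruth(
        kind="hits",
        parameters={
            "n_a": n_a, "n_b": n_b, "ortholog_fraction": ortholog_fraction,
            "evalue_range": list(evalue_range),
            "decoy_hits_per_gene": decoy_hits_per_gene, "seed": seed,
        },
        records=pd.DataFrame(pairs, columns=["id_a", "id_b"]),
    )
    return forward, reverse, truth


def write_lfq_tsv(path, matrix: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Write the LFQ TSV dialect: missing entries stored as 0 intensity."""
    out = meta.copy()
    out.insert(0, "ProteinID", matrix.index)
    linear = np.exp2(matrix)
    for col in matrix.columns:
        out[col] = linear[col].fillna(0.0).to_numpy()
    out.to_csv(path, sep="\t", index=False)
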