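"""Synthetic data generators: brain-like meshes, strip montages, coupled
oscillator pairs with known phase locking, and ERP-structured recordings.

These generators make every cortimap operation exercisable without any
external data.  The "brain" is an ellipsoidal icosphere (default extents
140 x 170 x 120 mm, roughly an adult head's left-right, front-back and
top-bottom spans): no algorithm in scope depends on cortical folding, so
a smooth closed surface suffices.  Strip montages emulate 1 x 16 subdural
strips at 10 mm contact spacing; the case-study montage lays four of them
over the left lateral aspect (channels 1-16, 17-32, 33-48, 49-64).

All generators are deterministic under a fixed seed; the seed changes
only the noise, never the structure.
"""

from __future__ import annotations

import numpy as np
import trimesh as _trimesh

from .errors import DomainError, PlacementError
from .mesh_model import TriMesh, import_mesh
from .registration import ElectrodeSet, Ray, intersect, place
from .signal_analysis import Recording

DEFAULT_BRAIN_EXTENTS_MM = (140.0, 170.0, 120.0)  # x (L-R), y (P-A), z (I-S)


def make_brain_mesh(subdivisions: int = 3,
                    scale_mm=DEFAULT_BRAIN_EXTENTS_MM) -> TriMesh:
    """Closed brain-like ellipsoid: an icosphere (10*4^s + 2 vertices)
    scaled anisotropically to the given full extents in mm."""
    if subdivisions < 0:
        raise DomainError("subdivisions must be >= 0")
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    half = 0.5 * np.asarray(scale_mm, dtype=np.float64)
    return import_mesh(np.asarray(ico.vertices) * half,
                       np.asarray(ico.faces))


def _project_to_surface(mesh: TriMesh, point: np.ndarray,
                        inward: np.ndarray):
    """Ray-cast ``point`` onto the mesh from well outside along
    ``inward``."""
    h = 2.0 * mesh.bbox_diagonal()
    inward = inward / np.linalg.norm(inward)
    hit = intersect(Ray(origin=point - h * inward, direction=inward), mesh)
    if hit is None:
        raise PlacementError("strip runs off the mesh silhouette")
    return hit


def make_strip(mesh: TriMesh, n_contacts: int, spacing_mm: float,
               start_point, direction,
               eset: ElectrodeSet | None = None) -> ElectrodeSet:
    """March a 1 x n strip across the surface.

    Each next contact steps along the local tangent in ``direction`` and
    is projected back onto the surface by ray casting from outside; the
    step length is iterated so the straight-line (chord) distance between
    consecutive contacts matches ``spacing_mm`` closely.
    """
    if n_contacts < 1:
        raise DomainError("n_contacts must be >= 1")
    if spacing_mm <= 0:
        raise DomainError("spacing_mm must be > 0")
    eset = eset if eset is not None else ElectrodeSet()
    centroid = mesh.centroid()
    p = np.asarray(start_point, dtype=np.float64)
    hit = _project_to_surface(mesh, p, centroid - p)
    normals = mesh.face_normals()
    p = hit.point
    eset = place(eset, p)
    d = np.asarray(direction, dtype=np.float64)
    for _ in range(n_contacts - 1):
        nrm = normals[hit.face_index]
        tang = d - np.dot(d, nrm) * nrm
        tn = np.linalg.norm(tang)
        if tn < 1e-9:
            raise PlacementError("strip direction degenerate "
                                 "(parallel to the surface normal)")
        tang /= tn
        step = spacing_mm
        q, nxt = None, None
        for _ in range(12):  # fixed-point iteration on the chord length
            nxt = _project_to_surface(mesh, p + step * tang, -nrm)
            chord = np.linalg.norm(nxt.point - p)
            if abs(chord - spacing_mm) < 1e-3 * spacing_mm:
                break
            step *= spacing_mm / max(chord, 1e-9)
        hit, q = nxt, nxt.point
        d = q - p  # carry the marching direction along the surface
        p = q
        eset = place(eset, p)
    return eset


def make_case_study_montage(mesh: TriMesh) -> ElectrodeSet:
    """Four 16-contact strips over the left lateral surface, channels
    numbered 1-16, 17-32, 33-48 and 49-64 in strip order (superior to
    inferior), 10 mm contact spacing."""
    half_y = 0.5 * (mesh.vertices[:, 1].max() - mesh.vertices[:, 1].min())
    x_left = mesh.vertices[:, 0].min()
    z_levels = (40.0, 13.0, -13.0, -40.0)
    zc = mesh.centroid()[2]
    y0 = -0.8 * half_y
    eset = ElectrodeSet()
    for z in z_levels:
        start = np.array([x_left * 1.5, y0, zc + z])
        eset = make_strip(mesh, n_contacts=16, spacing_mm=10.0,
                          start_point=start, direction=(0.0, 1.0, 0.0),
                          eset=eset)
    return eset


def make_coupled_pair(kappa: float, fs: float = 1000.0,
                      duration_s: float = 100.0, carrier_hz: float = 6.0,
                      seed: int = 0, return_phases: bool = False):
    """Two-channel oscillator pair with a known degree of phase locking.

    The channels share a carrier; their instantaneous phase difference is
    drawn i.i.d. per sample from a von Mises(0, kappa) law, so the
    population phase-locking value is the Bessel ratio
    ``I1(kappa) / I0(kappa)`` (0 at kappa=0, -> 1 as kappa -> inf).

    Returns the two-channel :class:`Recording`; with
    ``return_phases=True`` also the (2, n) ground-truth phase array, for
    validating the PLV statistic against the closed form without the
    phase-estimation step in between.
    """
    if kappa < 0:
        raise DomainError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phi1 = 2 * np.pi * carrier_hz * t
    dphi = rng.vonmises(0.0, kappa, size=n)
    phi2 = phi1 - dphi
    phases = np.vstack([phi1, phi2])
    rec = Recording(data=np.cos(phases), fs=fs,
                    events=np.empty(0, dtype=np.int64))
    return (rec, phases) if return_phases else rec


def erp_template(fs: float, post_ms: float = 3500.0) -> np.ndarray:
    """The known post-stimulus waveform used by :func:`make_erp_dataset`:
    a damped 8 Hz oscillation starting 200 ms after onset, peak ~50 uV."""
    t = np.arange(int(round(post_ms * fs / 1000.0))) / fs
    onset = 0.2
    active = t >= onset
    tpl = np.zeros_like(t)
    tt = t[active] - onset
    tpl[active] = 50.0 * np.exp(-tt / 0.4) * np.sin(2 * np.pi * 8.0 * tt)
    return tpl


def make_erp_dataset(n_trials: int = 100, n_channels: int = 64,
                     fs: float = 600.0, snr: float = 1.0,
                     seed: int = 0) -> Recording:
    """ERP-structured recording emulating a stimulus-response task.

    Every event adds the :func:`erp_template` waveform, scaled by a
    smooth per-channel gain profile (two active regions, one of them over
    the 49-64 channel range), on top of white noise.  ``snr`` is the RMS
    of the strongest channel's template (over the template's support)
    divided by the noise SD (``snr=inf`` gives a noiseless recording).
    Inter-trial intervals are jittered around 4.6 s and every event is
    window-safe for the default (-800, +3500) ms epoch.
    """
    if n_trials < 1:
        raise DomainError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    # event timing is structure, not noise: jitter comes from a fixed
    # stream so different seeds share an identical trial schedule
    iti = 4.6 + np.random.default_rng(716253).uniform(0.0, 0.4,
                                                      size=n_trials)
    onsets_s = 1.0 + np.concatenate([[0.0], np.cumsum(iti[:-1])])
    events = np.round(onsets_s * fs).astype(np.int64)
    n_samples = int(events[-1] + round(3.6 * fs))
    ch = np.arange(n_channels)
    gains = (0.15 + np.exp(-((ch - 0.85 * n_channels) / 4.0) ** 2)
             + 0.6 * np.exp(-((ch - 0.15 * n_channels) / 4.0) ** 2))
    tpl = erp_template(fs)
    if np.isinf(snr):
        data = np.zeros((n_channels, n_samples))
    else:
        support = tpl != 0.0
        tpl_rms = float(np.sqrt(np.mean(tpl[support] ** 2)))
        noise_sd = tpl_rms * gains.max() / snr
        data = rng.normal(0.0, noise_sd, size=(n_channels, n_samples))
    for ev in events:
        seg = min(len(tpl), n_samples - ev)
        data[:, ev:ev + seg] += gains[:, None] * tpl[None, :seg]
    return Recording(data=data, fs=fs, events=events)
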