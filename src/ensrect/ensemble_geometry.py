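"""Rigid-body superposition and the joint principal-component space.

Ensembles are superposed onto a common reference by the Kabsch algorithm
(proper rotations only), then Cartesian PCA on the flattened Cα coordinates
defines a shared low-dimensional space.  The leading components — PC1, PC2 —
are the collective coordinates on which downsampling and weighted-ensemble
binning operate; the retained subspace (85% explained variance by default)
is where trajectory reweighting happens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Structure, StructureEnsemble

__all__ = ["PCSpace", "kabsch_superpose", "align_ensemble", "fit_pca", "project"]


@dataclass
class PCSpace:
    """Joint principal-component space of aligned Cα coordinates.

    reference : (M, 3) Cα coordinates of the alignment reference
    mean_coords : (3M,) mean of the flattened aligned coordinates
    axes : (K, 3M) orthonormal principal axes, variance-ordered (rows)
    variance_fractions : per-axis explained-variance fractions, non-increasing
    n_retained : number of axes needed to reach the variance cutoff
    """

    reference: np.ndarray
    mean_coords: np.ndarray
    axes: np.ndarray
    variance_fractions: np.ndarray
    n_retained: int
    variances: np.ndarray | None = None

    def save(self, path) -> None:
        """Serialize to a .npz archive (keys mirror the field names)."""
        np.savez(
            path,
            reference=self.reference,
            mean_coords=self.mean_coords,
            axes=self.axes,
            variance_fractions=self.variance_fractions,
            n_retained=np.array(self.n_retained),
            variances=self.variances if self.variances is not None else np.zeros(0),
        )

    @classmethod
    def load(cls, path) -> "PCSpace":
        with np.load(path) as f:
            variances = f["variances"]
            return cls(
                reference=f["reference"],
                mean_coords=f["mean_coords"],
                axes=f["axes"],
                variance_fractions=f["variance_fractions"],
                n_retained=int(f["n_retained"]),
                variances=variances if variances.size else None,
            )


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-RMSD rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(aligned, rmsd)``.  The transform is rotation + translation
    only; reflections are forbidden by the determinant correction, so the
    result is a physically realizable superposition.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"atom-count mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("superposition requires at least 3 atoms of shape (M, 3)")

    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    # Kabsch: SVD of the covariance, with a sign flip to exclude reflections.
    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt
    aligned = mob_c @ rot + reference.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=1))))
    return aligned, rmsd


def align_ensemble(ensemble: StructureEnsemble, reference: np.ndarray) -> StructureEnsemble:
    """Superpose every member onto ``reference``; weights are untouched."""
    new_members = []
    for m in ensemble.members:
        aligned, _ = kabsch_superpose(m.coords, reference)
        new_members.append(
            Structure(
                atom_names=list(m.atom_names),
                residue_ids=list(m.residue_ids),
                coords=aligned,
                model_id=m.model_id,
            )
        )
    return StructureEnsemble(
        members=new_members,
        weights=np.array(ensemble.weights, copy=True),
        source_label=ensemble.source_label,
    )


def _fix_axis_signs(axes: np.ndarray) -> np.ndarray:
    # Deterministic sign convention: largest-magnitude loading positive.
    out = axes.copy()
    for i, ax in enumerate(out):
        j = int(np.argmax(np.abs(ax)))
        if ax[j] < 0:
            out[i] = -ax
    return out


def fit_pca(
    aligned: StructureEnsemble | np.ndarray,
    variance_cutoff: float = 0.85,
    reference: np.ndarray | None = None,
) -> PCSpace:
    """Cartesian PCA of an aligned ensemble.

    Covariance of the 3M-dimensional flattened coordinates, centered on the
    ensemble mean (unweighted, all atoms equal).  ``n_retained`` is the
    smallest m whose cumulative variance fraction reaches ``variance_cutoff``.
    """
    if not (0.0 < variance_cutoff <= 1.0):
        raise ValueError(f"variance_cutoff must be in (0, 1], got {variance_cutoff}")
    if isinstance(aligned, StructureEnsemble):
        coords = aligned.coord_array()
        if reference is None:
            reference = aligned.members[0].coords
    else:
        coords = np.asarray(aligned, dtype=float)
        if reference is None:
            reference = coords[0]
    n = coords.shape[0]
    if n < 2:
        raise ValueError("PCA requires at least 2 members")
    x = coords.reshape(n, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD of the centered data matrix; eigenvalues of the covariance follow.
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    variances = s**2 / (n - 1)
    total = variances.sum()
    fractions = variances / total if total > 0 else np.zeros_like(variances)
    axes = _fix_axis_signs(vt)
    cum = np.cumsum(fractions)
    n_retained = int(np.searchsorted(cum, variance_cutoff - 1e-12) + 1)
    n_retained = min(n_retained, len(fractions))
    return PCSpace(
        reference=np.asarray(reference, dtype=float),
        mean_coords=mean,
        axes=axes,
        variance_fractions=fractions,
        n_retained=n_retained,
        variances=variances,
    )


def project(
    coords,
    space: PCSpace,
    n_components: int | None = None,
    superpose: bool = False,
) -> np.ndarray:
    """Project coordinates onto the leading principal axes.

    ``coords`` may be a single (M, 3) conformation, an (N, M, 3) batch, or a
    :class:`~ensrect.structure_io.StructureEnsemble`.  With ``superpose=True``
    each conformation is first Kabsch-superposed onto ``space.reference``.
    Returns projections of shape (n_components,) or (N, n_components).
    """
    if n_components is None:
        n_components = space.n_retained
    if n_components > space.axes.shape[0]:
        raise ValueError(
            f"requested {n_components} components but only {space.axes.shape[0]} axes exist"
        )
    if isinstance(coords, StructureEnsemble):
        coords = coords.coord_array()
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    batch = coords[None] if single else coords
    if superpose:
        batch = np.stack(
            [kabsch_superpose(c, space.reference)[0] for c in batch]
        )
    flat = batch.reshape(batch.shape[0], -1)
    proj = (flat - space.mean_coords) @ space.axes[:n_components].T
    return proj[0] if single else proj


def reconstruct(projections: np.ndarray, space: PCSpace) -> np.ndarray:
    """Invert :func:`project` (with as many axes as the projection carries)."""
    projections = np.atleast_2d(np.asarray(projections, dtype=float))
    k = projections.shape[1]
    flat = projections @ space.axes[:k] + space.mean_coords
    return flat.reshape(projections.shape[0], -1, 3)
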