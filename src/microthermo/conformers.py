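"""Conformer ensemble curation: energy windows, RMSD clustering, selection.

The curation pipeline mirrors a standard multi-conformer QM workflow:

1. discard structures with a force-field energy more than a window (default
   20 kcal/mol) above the apparent global minimum of the microstate;
2. greedy leader clustering in order of increasing energy — the minimum
   seeds the first cluster, each subsequent structure is discarded if it
   lies within the RMSD cutoff (default 0.5 A) of any accepted
   representative, otherwise it founds a new cluster;
3. after QM re-optimization, a second purely RMSD-based pass with the same
   greedy rule removes conformations that converged to the same minimum;
4. up to k (default 5) lowest-energy survivors are kept.

RMSD between two conformations is the least-squares superposition residual
(Kabsch algorithm, proper rotations only so chirality is preserved),
optionally minimized over caller-supplied atom symmetry permutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConformerGeometry",
    "ClusterConfig",
    "kabsch_rmsd",
    "best_rmsd",
    "energy_window_filter",
    "greedy_rmsd_cluster",
    "dedup_post_optimization",
    "select_top_k",
    "curation_pipeline",
]


@dataclass(frozen=True)
class ConformerGeometry:
    """One conformation: coordinates, element labels and a stage energy."""

    conformer_id: str
    coordinates: np.ndarray
    atom_labels: tuple[str, ...]
    energy: float
    symmetry_permutations: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError(
                f"conformer {self.conformer_id!r}: coordinates must be N x 3 "
                f"with N >= 1, got shape {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"conformer {self.conformer_id!r}: non-finite coordinates")
        if len(self.atom_labels) != coords.shape[0]:
            raise ValueError(
                f"conformer {self.conformer_id!r}: {len(self.atom_labels)} atom "
                f"labels for {coords.shape[0]} atoms"
            )
        if not math.isfinite(self.energy):
            raise ValueError(f"conformer {self.conformer_id!r}: non-finite energy")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "atom_labels", tuple(self.atom_labels))
        perms = tuple(tuple(int(i) for i in p) for p in self.symmetry_permutations)
        for p in perms:
            _check_permutation(p, self.atom_labels)
        object.__setattr__(self, "symmetry_permutations", perms)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class ClusterConfig:
    """Curation parameters.

    Defaults follow the submission workflow (20 kcal/mol window, 0.5 A
    cutoff, 5 representatives); the alternative sampling workflow uses a
    5 kcal/mol window and a 1.5 A cutoff.
    """

    energy_window: float = 20.0
    rmsd_cutoff: float = 0.5
    max_representatives: int = 5
    heavy_atoms_only: bool = False

    def __post_init__(self) -> None:
        if not (self.energy_window > 0 and self.rmsd_cutoff > 0
                and self.max_representatives > 0):
            raise ValueError("all cluster parameters must be positive")


def _check_permutation(perm: tuple[int, ...], labels: tuple[str, ...]) -> None:
    n = len(labels)
    if sorted(perm) != list(range(n)):
        raise ValueError(f"invalid permutation (not a bijection on 0..{n-1}): {perm}")
    for i, j in enumerate(perm):
        if labels[i] != labels[j]:
            raise ValueError(
                f"permutation maps atom {j} ({labels[j]}) onto position "
                f"{i} ({labels[i]}); element labels must be preserved"
            )


def _select_atoms(g: ConformerGeometry, heavy_only: bool) -> np.ndarray:
    if not heavy_only:
        return g.coordinates
    mask = np.array([lab.upper() != "H" for lab in g.atom_labels])
    if not mask.any():
        return g.coordinates
    return g.coordinates[mask]


def _kabsch(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal proper-rotation + translation superposition."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(a.T @ b)
    # proper rotation only: flip the smallest singular direction if needed
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    rot = u @ flip @ vt
    # explicit residual (not the trace identity) to avoid cancellation error
    diff = a @ rot - b
    return math.sqrt((diff * diff).sum() / a.shape[0])


def kabsch_rmsd(
    a: ConformerGeometry, b: ConformerGeometry, heavy_atoms_only: bool = False
) -> float:
    """Minimum RMSD between two conformations over rigid motions.

    Least-squares superposition with proper rotations only (no
    reflections), so enantiomers are not mapped onto each other.
    """
    if a.n_atoms != b.n_atoms or a.atom_labels != b.atom_labels:
        raise ValueError(
            f"atom mismatch between {a.conformer_id!r} ({a.n_atoms} atoms, "
            f"{a.atom_labels}) and {b.conformer_id!r} ({b.n_atoms} atoms, "
            f"{b.atom_labels})"
        )
    return _kabsch(
        _select_atoms(a, heavy_atoms_only), _select_atoms(b, heavy_atoms_only)
    )


def best_rmsd(
    a: ConformerGeometry,
    b: ConformerGeometry,
    permutations: Sequence[Sequence[int]] | None = None,
    heavy_atoms_only: bool = False,
) -> float:
    """Superposition RMSD minimized over atom symmetry permutations of b.

    ``permutations`` defaults to ``b.symmetry_permutations``; with none
    supplied this is plain :func:`kabsch_rmsd` (label-order matching).
    """
    if permutations is None:
        permutations = b.symmetry_permutations
    if not permutations:
        return kabsch_rmsd(a, b, heavy_atoms_only)
    best = math.inf
    for perm in permutations:
        p = tuple(int(i) for i in perm)
        _check_permutation(p, b.atom_labels)
        permuted = ConformerGeometry(
            conformer_id=b.conformer_id,
            coordinates=b.coordinates[list(p)],
            atom_labels=tuple(b.atom_labels[i] for i in p),
            energy=b.energy,
        )
        best = min(best, kabsch_rmsd(a, permuted, heavy_atoms_only))
    return best


def energy_window_filter(
    conformers: Sequence[ConformerGeometry], config: ClusterConfig | None = None
) -> list[ConformerGeometry]:
    """Keep structures within the energy window above the apparent minimum.

    The boundary is inclusive (exactly window above the minimum is kept);
    the minimum itself always survives; input order is preserved.
    """
    config = config or ClusterConfig()
    if not conformers:
        raise ValueError("empty conformer list")
    e_min = min(c.energy for c in conformers)
    return [c for c in conformers if c.energy - e_min <= config.energy_window]


def _stable_energy_sort(
    conformers: Sequence[ConformerGeometry],
) -> list[ConformerGeometry]:
    return sorted(conformers, key=lambda c: c.energy)  # sorted() is stable


def greedy_rmsd_cluster(
    conformers: Sequence[ConformerGeometry], config: ClusterConfig | None = None
) -> list[ConformerGeometry]:
    """Greedy leader clustering in ascending energy order.

    The lowest-energy structure seeds the first cluster; every subsequent
    structure (in order of increasing energy, ties broken by input order)
    is kept as a new cluster representative iff its best RMSD to *every*
    already-accepted representative is >= the cutoff, otherwise it is
    discarded as redundant.  Returns representatives in acceptance order.
    """
    config = config or ClusterConfig()
    if not conformers:
        raise ValueError("empty conformer list")
    reps: list[ConformerGeometry] = []
    for cand in _stable_energy_sort(conformers):
        if all(
            best_rmsd(rep, cand, heavy_atoms_only=config.heavy_atoms_only)
            >= config.rmsd_cutoff
            for rep in reps
        ):
            reps.append(cand)
    return reps


def dedup_post_optimization(
    conformers: Sequence[ConformerGeometry], config: ClusterConfig | None = None
) -> list[ConformerGeometry]:
    """Remove conformations that converged to the same minimum during QM
    optimization: the same greedy RMSD pass, ordered by the QM energy,
    with no energy window."""
    return greedy_rmsd_cluster(conformers, config)


def select_top_k(
    conformers: Sequence[ConformerGeometry], k: int
) -> list[ConformerGeometry]:
    """The k lowest-energy conformers (fewer if fewer exist), ascending
    energy, ties broken by input order."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return _stable_energy_sort(conformers)[:k]


def curation_pipeline(
    conformers: Sequence[ConformerGeometry], config: ClusterConfig | None = None
) -> list[ConformerGeometry]:
    """Full curation: window -> greedy cluster -> dedup -> top-k.

    Idempotent: re-running on its own output changes nothing.
    """
    config = config or ClusterConfig()
    kept = energy_window_filter(conformers, config)
    kept = greedy_rmsd_cluster(kept, config)
    kept = dedup_post_optimization(kept, config)
    return select_top_k(kept, config.max_representatives)
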