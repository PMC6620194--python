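"""Two-round PCR simulator with template switching and micelle partitioning.

Chimeric molecules form when an incompletely extended strand re-anneals, at the
constant spacer, to a heterologous template and completes synthesis there: the
product carries the BC of one clone and the ROI of another.  The simulator
models amplification at the species-abundance level: within a compartment every
species doubles each cycle, and a fraction ``switch_prob`` of the newly made
copies has its ROI reassigned from the compartment's abundance-weighted ROI
marginal.  Switching moves copies between species but never creates or destroys
them, so the total abundance after ``c`` cycles is exactly ``initial * 2**c``.

Because switching preserves both the BC and the ROI marginals, the per-cycle
recursion has an exact closed form,

    A_t = (2 - p)**t * A_0 + tot0 * (2**t - (2 - p)**t) * outer(rho, kappa),

with ``rho``/``kappa`` the normalised initial BC/ROI marginals.  The public
:func:`amplify` runs the per-cycle recursion; the closed form drives the
vectorised handling of millions of micelles and of bulk (conventional)
compartments, and the two are interchangeable to floating-point accuracy.

Species are tracked as ``(clone index, ROI-sequence id)`` pairs; a species is
chimeric iff its ROI sequence differs from its clone's own ROI (a switch that
lands on an identical ROI sequence is indistinguishable from the genuine
molecule and is not chimeric).
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mprachim.design import PlasmidLibrary, build_read_layout

__all__ = [
    "ProtocolParams",
    "ErrorModel",
    "SpeciesPool",
    "Partition",
    "EmptyCarryoverError",
    "partition_templates",
    "amplify",
    "run_protocol",
    "emit_fastq",
    "expected_chimeric_fraction",
    "switch_prob_for_target",
]


class EmptyCarryoverError(RuntimeError):
    """Carryover thinning left zero molecules to seed round 2."""


@dataclass(frozen=True)
class ProtocolParams:
    """Parameters of the two-round amplification protocol.

    ``switch_prob`` is the per-cycle probability that a newly synthesized copy
    is incompletely extended and resumes on another co-compartment template; it
    is the model's proxy for the elongation-time setting (shorter elongation
    leaves more incomplete strands, i.e. a larger ``switch_prob``).
    ``carryover_fraction`` is the pipetted fraction of round-1 product used to
    seed round 2 (1/100 by default).
    """

    mode: str = "emulsion"
    template_molecules: int = 2_000_000
    micelle_count: int = 10_000_000_000
    cycles_round1: int = 15
    cycles_round2: int = 18
    carryover_fraction: float = 0.01
    switch_prob: float = 1e-3

    def __post_init__(self) -> None:
        if self.mode not in ("emulsion", "conventional"):
            raise ValueError(f"mode must be 'emulsion' or 'conventional', got {self.mode!r}")
        if self.template_molecules < 1 or self.micelle_count < 1:
            raise ValueError("template_molecules and micelle_count must be >= 1")
        if self.cycles_round1 < 1 or self.cycles_round2 < 1:
            raise ValueError("cycle counts must be >= 1")
        if not 0.0 < self.carryover_fraction <= 1.0:
            raise ValueError("carryover_fraction must be in (0, 1]")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0, 1]")


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution model lumping PCR and sequencing errors."""

    sub_rate: float = 1e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.sub_rate <= 0.05:
            raise ValueError("sub_rate must be in [0, 0.05]")


class SpeciesPool:
    """Abundances of (BC, ROI) species, with an optional low-rank component.

    The pool is the sum of an explicit part (``species`` ids with
    ``abundance``) and an optional rank-1 part of mass ``rank1_mass``
    distributed as ``outer(rank1_rho, rank1_kappa)`` over all
    (clone, ROI-sequence) combinations.  The rank-1 part is how bulk
    compartments with tens of thousands of clones are represented without
    materialising every cross combination.
    """

    def __init__(
        self,
        library: PlasmidLibrary,
        species: np.ndarray,
        abundance: np.ndarray,
        rank1_mass: float = 0.0,
        rank1_rho: np.ndarray | None = None,
        rank1_kappa: np.ndarray | None = None,
    ) -> None:
        self.library = library
        self.n_roi = len(library.roi_seqs)
        species = np.asarray(species, dtype=np.int64)
        abundance = np.asarray(abundance, dtype=float)
        if species.shape != abundance.shape:
            raise ValueError("species and abundance must have the same shape")
        if np.any(abundance < 0):
            raise ValueError("abundances must be >= 0")
        # Aggregate duplicate species ids.
        if species.size:
            uniq, inv = np.unique(species, return_inverse=True)
            self.species = uniq
            self.abundance = np.bincount(inv, weights=abundance, minlength=uniq.size)
        else:
            self.species = species
            self.abundance = abundance
        self.rank1_mass = float(rank1_mass)
        self.rank1_rho = rank1_rho
        self.rank1_kappa = rank1_kappa
        if rank1_mass > 0 and (rank1_rho is None or rank1_kappa is None):
            raise ValueError("rank-1 component requires rho and kappa")

    # -- species id helpers -------------------------------------------------
    def sid(self, clone_idx: int, roi_id: int) -> int:
        return clone_idx * self.n_roi + roi_id

    def _split(self, ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return ids // self.n_roi, ids % self.n_roi

    # -- totals -------------------------------------------------------------
    @property
    def total(self) -> float:
        return float(self.abundance.sum()) + self.rank1_mass

    @property
    def chimeric_mass(self) -> float:
        mass = 0.0
        if self.species.size:
            clone, roi = self._split(self.species)
            chim = roi != self.library.clone_roi_id[clone]
            mass += float(self.abundance[chim].sum())
        if self.rank1_mass > 0:
            own = float(
                np.sum(self.rank1_rho * self.rank1_kappa[self.library.clone_roi_id])
            )
            mass += self.rank1_mass * (1.0 - own)
        return mass

    @property
    def chimeric_fraction(self) -> float:
        tot = self.total
        return self.chimeric_mass / tot if tot > 0 else 0.0

    def is_chimeric(self, bc: str, roi: str) -> bool:
        idx = self.library.bcs.index(bc)
        return roi != self.library.clones[idx].roi

    # -- sampling -----------------------------------------------------------
    def sample_molecule_counts(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Multinomial draw of ``n`` molecules, returned as species counts.

        Scales to billions of molecules because only per-species counts are
        materialised, never per-molecule arrays.
        """
        tot = self.total
        if tot <= 0:
            raise ValueError("pool is empty")
        n_rank1 = 0
        if self.rank1_mass > 0:
            n_rank1 = int(rng.binomial(n, self.rank1_mass / tot))
        n_expl = n - n_rank1
        ids: list[np.ndarray] = []
        cnts: list[np.ndarray] = []
        if n_expl:
            c = rng.multinomial(n_expl, self.abundance / self.abundance.sum())
            keep = c > 0
            ids.append(self.species[keep])
            cnts.append(c[keep])
        if n_rank1:
            clone_counts = rng.multinomial(n_rank1, self.rank1_rho)
            for ci in np.flatnonzero(clone_counts):
                rc = rng.multinomial(clone_counts[ci], self.rank1_kappa)
                keep = rc > 0
                ids.append(ci * self.n_roi + np.flatnonzero(keep))
                cnts.append(rc[keep])
        if not ids:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        all_ids = np.concatenate(ids)
        all_cnts = np.concatenate(cnts)
        uniq, inv = np.unique(all_ids, return_inverse=True)
        return uniq, np.bincount(inv, weights=all_cnts).astype(np.int64)

    def sample_molecules(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` molecule identities abundance-weighted.

        Returns per-molecule arrays of clone indices and ROI-sequence ids
        (unordered); use :meth:`sample_molecule_counts` when ``n`` is huge.
        """
        ids, cnts = self.sample_molecule_counts(n, rng)
        expanded = np.repeat(ids, cnts)
        return self._split(expanded)

    # -- export -------------------------------------------------------------
    def materialize(self, max_species: int = 5_000_000) -> "SpeciesPool":
        """Fold the rank-1 component into explicit species (small pools only)."""
        if self.rank1_mass <= 0:
            return self
        n_full = len(self.library) * self.n_roi
        if n_full > max_species:
            raise ValueError(
                f"materialising the rank-1 component would create {n_full} species"
            )
        full = self.rank1_mass * np.outer(self.rank1_rho, self.rank1_kappa)
        ids = np.arange(n_full, dtype=np.int64)
        mass = full.ravel()
        keep = mass > 0
        species = np.concatenate([self.species, ids[keep]])
        abundance = np.concatenate([self.abundance, mass[keep]])
        return SpeciesPool(self.library, species, abundance)

    def as_dict(self) -> dict[tuple[str, str], float]:
        pool = self.materialize()
        out: dict[tuple[str, str], float] = {}
        clone, roi = pool._split(pool.species)
        for c, r, a in zip(clone, roi, pool.abundance):
            if a > 0:
                out[(self.library.clones[c].bc, self.library.roi_seqs[r])] = float(a)
        return out

    def to_frame(self) -> pd.DataFrame:
        pool = self.materialize()
        clone, roi = pool._split(pool.species)
        bcs = np.array(self.library.bcs, dtype=object)
        rois = np.array(self.library.roi_seqs, dtype=object)
        return pd.DataFrame(
            {
                "bc": bcs[clone],
                "roi": rois[roi],
                "abundance": pool.abundance,
                "chimeric": roi != self.library.clone_roi_id[clone],
            }
        )


@dataclass
class Partition:
    """Assignment of template molecules to compartments.

    ``molecule_clone`` holds the clone index of each template molecule and
    ``compartment_of`` the compartment it landed in (all zeros in conventional
    mode, where there is a single compartment).
    """

    molecule_clone: np.ndarray
    compartment_of: np.ndarray
    n_compartments: int

    def compartments(self) -> Iterable[np.ndarray]:
        """Clone indices per occupied compartment (use on small partitions)."""
        order = np.argsort(self.compartment_of, kind="stable")
        comp = self.compartment_of[order]
        mol = self.molecule_clone[order]
        starts = np.concatenate([[0], np.flatnonzero(np.diff(comp)) + 1, [comp.size]])
        for a, b in zip(starts[:-1], starts[1:]):
            yield mol[a:b]

    def occupancy_counts(self) -> np.ndarray:
        """Number of molecules per occupied compartment."""
        _, counts = np.unique(self.compartment_of, return_counts=True)
        return counts


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def partition_templates(
    library: PlasmidLibrary,
    params: ProtocolParams,
    seed: int | np.random.Generator | None = None,
) -> Partition:
    """Assign template molecules independently and uniformly to micelles.

    Molecule identities are drawn from the library's template weights.  In
    conventional mode all molecules share one compartment.
    """
    rng = _as_rng(seed)
    T = params.template_molecules
    mol = rng.choice(len(library), size=T, p=library.weights)
    if params.mode == "conventional":
        return Partition(mol, np.zeros(T, dtype=np.int64), 1)
    comp = rng.integers(0, params.micelle_count, size=T)
    return Partition(mol, comp, params.micelle_count)


# ---------------------------------------------------------------------------
# amplification
# ---------------------------------------------------------------------------


def _compartment_counts(
    compartment: Mapping[tuple[int, int], float] | Sequence[tuple[int, int]],
) -> dict[tuple[int, int], float]:
    if isinstance(compartment, Mapping):
        return {k: float(v) for k, v in compartment.items()}
    counts: dict[tuple[int, int], float] = {}
    for key in compartment:
        counts[tuple(key)] = counts.get(tuple(key), 0.0) + 1.0
    return counts


def amplify(
    compartment: Mapping[tuple[int, int], float] | Sequence[tuple[int, int]],
    cycles: int,
    switch_prob: float,
    library: PlasmidLibrary,
) -> SpeciesPool:
    """Deterministic expected-value amplification of one compartment.

    ``compartment`` is a multiset of molecules given either as a sequence of
    ``(clone index, ROI-sequence id)`` tuples or as a mapping from such tuples
    to counts.  Runs the per-cycle recursion: each cycle every species doubles
    and a ``switch_prob`` fraction of the new copies has its ROI redrawn from
    the compartment's abundance-weighted ROI marginal.
    """
    counts = _compartment_counts(compartment)
    if not counts:
        raise ValueError("compartment must be non-empty")
    p = switch_prob
    rows = sorted({k[0] for k in counts})
    cols = sorted({k[1] for k in counts})
    ri = {b: i for i, b in enumerate(rows)}
    ci = {r: j for j, r in enumerate(cols)}
    A = np.zeros((len(rows), len(cols)))
    for (b, r), n in counts.items():
        A[ri[b], ci[r]] += n
    for _ in range(cycles):
        col_marg = A.sum(axis=0)
        tot = col_marg.sum()
        A = (2.0 - p) * A + p * np.outer(A.sum(axis=1), col_marg / tot)
    n_roi = len(library.roi_seqs)
    ids = (np.asarray(rows)[:, None] * n_roi + np.asarray(cols)[None, :]).ravel()
    return SpeciesPool(library, ids, A.ravel())


def _bulk_closed_form(
    library: PlasmidLibrary,
    species: np.ndarray,
    counts: np.ndarray,
    cycles: int,
    p: float,
) -> SpeciesPool:
    """Closed-form amplification of one large compartment.

    Exact equivalent of the per-cycle recursion: the surviving original
    component keeps the input species, the mixed component is rank-1 in the
    (conserved, normalised) BC and ROI marginals.
    """
    n_roi = len(library.roi_seqs)
    tot0 = counts.sum()
    beta = (2.0 - p) ** cycles
    mix = tot0 * (2.0**cycles - beta)
    clone, roi = species // n_roi, species % n_roi
    rho = np.bincount(clone, weights=counts, minlength=len(library)) / tot0
    kappa = np.bincount(roi, weights=counts, minlength=n_roi) / tot0
    return SpeciesPool(
        library,
        species,
        counts * beta,
        rank1_mass=float(mix),
        rank1_rho=rho,
        rank1_kappa=kappa,
    )


def _amplify_pairs(
    b1: np.ndarray,
    r1: np.ndarray,
    b2: np.ndarray,
    r2: np.ndarray,
    cycles: int,
    p: float,
    n_roi: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised closed form for compartments holding exactly two molecules."""
    beta = (2.0 - p) ** cycles
    mix = 2.0 * (2.0**cycles - beta)  # tot0 = 2
    s11 = b1 * n_roi + r1
    s22 = b2 * n_roi + r2
    s12 = b1 * n_roi + r2
    s21 = b2 * n_roi + r1
    same = s11 == s22
    bsame = (b1 == b2) & ~same
    rsame = (r1 == r2) & ~same
    diff = ~(same | bsame | rsame)
    ids = []
    mass = []
    if np.any(same):
        ids.append(s11[same])
        mass.append(np.full(same.sum(), 2.0 * 2.0**cycles))
    for m in (bsame, rsame):
        if np.any(m):
            ids.append(s11[m])
            ids.append(s22[m])
            half = np.full(m.sum(), beta + mix / 2.0)
            mass.extend([half, half])
    if np.any(diff):
        own = np.full(diff.sum(), beta + mix / 4.0)
        cross = np.full(diff.sum(), mix / 4.0)
        ids.extend([s11[diff], s22[diff], s12[diff], s21[diff]])
        mass.extend([own, own, cross, cross])
    if not ids:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return np.concatenate(ids), np.concatenate(mass)


def _amplify_partitioned(
    library: PlasmidLibrary,
    species_ids: np.ndarray,
    compartment_of: np.ndarray,
    cycles: int,
    p: float,
) -> SpeciesPool:
    """Amplify every occupied compartment and pool the products.

    Singleton compartments double without chimeras; two-molecule compartments
    use the vectorised closed form; larger (rare) compartments fall back to the
    generic closed form one by one.
    """
    n_roi = len(library.roi_seqs)
    order = np.argsort(compartment_of, kind="stable")
    comp = compartment_of[order]
    sp = species_ids[order]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(comp)) + 1])
    sizes = np.diff(np.concatenate([starts, [comp.size]]))

    ids_parts: list[np.ndarray] = []
    mass_parts: list[np.ndarray] = []

    singles = starts[sizes == 1]
    if singles.size:
        uniq, cnt = np.unique(sp[singles], return_counts=True)
        ids_parts.append(uniq)
        mass_parts.append(cnt * 2.0**cycles)

    pairs = starts[sizes == 2]
    if pairs.size:
        m1, m2 = sp[pairs], sp[pairs + 1]
        ids, mass = _amplify_pairs(
            m1 // n_roi, m1 % n_roi, m2 // n_roi, m2 % n_roi, cycles, p, n_roi
        )
        ids_parts.append(ids)
        mass_parts.append(mass)

    for a, size in zip(starts[sizes >= 3], sizes[sizes >= 3]):
        group = sp[a : a + size]
        uniq, cnt = np.unique(group, return_counts=True)
        sub = _bulk_closed_form(library, uniq, cnt.astype(float), cycles, p)
        # Materialise the tiny rank-1 outer product explicitly.
        clone, roi = uniq // n_roi, uniq % n_roi
        rows = np.unique(clone)
        cols = np.unique(roi)
        full = sub.rank1_mass * np.outer(sub.rank1_rho[rows], sub.rank1_kappa[cols])
        grid = (rows[:, None] * n_roi + cols[None, :]).ravel()
        ids_parts.extend([sub.species, grid])
        mass_parts.extend([sub.abundance, full.ravel()])

    return SpeciesPool(
        library, np.concatenate(ids_parts), np.concatenate(mass_parts)
    )


def run_protocol(
    library: PlasmidLibrary,
    params: ProtocolParams,
    rng: int | np.random.Generator | None = None,
) -> SpeciesPool:
    """Run the full two-round protocol and return the final pooled species.

    Round 1 partitions the template molecules (emulsion) or keeps them in one
    compartment (conventional) and amplifies.  A ``carryover_fraction``
    binomial thinning of the pooled product, with molecule identities resampled
    abundance-weighted, seeds round 2, which partitions afresh in emulsion mode.
    """
    rng = _as_rng(rng)
    p = params.switch_prob
    n_roi = len(library.roi_seqs)

    part = partition_templates(library, params, rng)
    mol_species = library.clone_roi_id[part.molecule_clone] + part.molecule_clone * n_roi
    if params.mode == "conventional":
        uniq, cnt = np.unique(mol_species, return_counts=True)
        pool1 = _bulk_closed_form(library, uniq, cnt.astype(float), params.cycles_round1, p)
    else:
        pool1 = _amplify_partitioned(
            library, mol_species, part.compartment_of, params.cycles_round1, p
        )

    n_carry = int(rng.binomial(int(round(pool1.total)), params.carryover_fraction))
    if n_carry == 0:
        raise EmptyCarryoverError(
            "carryover thinning left zero molecules; increase carryover_fraction "
            "or the template amount"
        )
    if params.mode == "conventional":
        ids, cnt = pool1.sample_molecule_counts(n_carry, rng)
        return _bulk_closed_form(library, ids, cnt.astype(float), params.cycles_round2, p)
    clone2, roi2 = pool1.sample_molecules(n_carry, rng)
    species2 = clone2 * n_roi + roi2
    comp2 = rng.integers(0, params.micelle_count, size=n_carry)
    return _amplify_partitioned(library, species2, comp2, params.cycles_round2, p)


def expected_chimeric_fraction(
    library: PlasmidLibrary, switch_prob: float, total_cycles: int
) -> float:
    """Expected chimeric fraction of a bulk (conventional) amplification.

    ``(1 - (1 - p/2)**c) * (1 - w)`` where ``w`` is the probability that a
    switch lands on the parent's own ROI sequence (marginal self-overlap).
    """
    kappa = np.bincount(
        library.clone_roi_id, weights=library.weights, minlength=len(library.roi_seqs)
    )
    w = float(np.sum(library.weights * kappa[library.clone_roi_id]))
    return (1.0 - (1.0 - switch_prob / 2.0) ** total_cycles) * (1.0 - w)


def switch_prob_for_target(
    library: PlasmidLibrary, target_fraction: float, total_cycles: int
) -> float:
    """Switch probability giving an expected bulk chimeric fraction.

    Inverse of :func:`expected_chimeric_fraction`; used to inject a chosen
    chimeric read fraction into conventional-mode simulations.
    """
    kappa = np.bincount(
        library.clone_roi_id, weights=library.weights, minlength=len(library.roi_seqs)
    )
    w = float(np.sum(library.weights * kappa[library.clone_roi_id]))
    inner = 1.0 - target_fraction / (1.0 - w)
    if inner <= 0:
        raise ValueError("target_fraction is not attainable for this library")
    return 2.0 * (1.0 - inner ** (1.0 / total_cycles))


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def emit_fastq(
    pool: SpeciesPool,
    sample: str,
    n_reads: int,
    error_model: ErrorModel,
    rng: int | np.random.Generator | None,
    path: str | Path,
    truth_path: str | Path | None = None,
    sidecar: Mapping | None = None,
    read_prefix: str = "read",
) -> pd.DataFrame:
    """Sample reads abundance-weighted from ``pool`` and write FASTQ + truth.

    Each read is the full-length amplicon of its source species carrying the
    ``sample`` index, with i.i.d. per-base substitutions at
    ``error_model.sub_rate`` and a constant quality string.  The returned truth
    table (also written to ``truth_path`` as TSV when given) records the source
    BC/ROI, the chimeric flag and whether any substitution hit the read.
    """
    if error_model.seed is not None and rng is None:
        rng = error_model.seed
    rng = _as_rng(rng)
    library = pool.library
    design = library.design
    layout = build_read_layout(design)
    if pool.total <= 0:
        raise ValueError("pool has no molecules to sequence")

    clone_idx, roi_id = pool.sample_molecules(n_reads, rng)
    perm = rng.permutation(n_reads)
    clone_idx, roi_id = clone_idx[perm], roi_id[perm]

    template = design.read_template(
        sample, library.clones[0].bc, library.roi_seqs[0]
    ).encode()
    base_row = np.frombuffer(template, dtype=np.uint8).copy()
    bc_mat = np.frombuffer(
        "".join(library.bcs).encode(), dtype=np.uint8
    ).reshape(len(library), design.bc_length)
    roi_mat = np.frombuffer(
        "".join(library.roi_seqs).encode(), dtype=np.uint8
    ).reshape(len(library.roi_seqs), design.roi_length)

    L = design.read_length
    qual = "I" * L
    mutated = np.zeros(n_reads, dtype=bool)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        chunk = 65536
        for start in range(0, n_reads, chunk):
            stop = min(start + chunk, n_reads)
            rows = np.tile(base_row, (stop - start, 1))
            rows[:, layout.bc[0] : layout.bc[1]] = bc_mat[clone_idx[start:stop]]
            rows[:, layout.roi[0] : layout.roi[1]] = roi_mat[roi_id[start:stop]]
            if error_model.sub_rate > 0:
                mask = rng.random(rows.shape) < error_model.sub_rate
                mask &= rows != ord("N")
                n_mut = int(mask.sum())
                if n_mut:
                    codes = _CODE[rows[mask]]
                    rows[mask] = _BASES[(codes + rng.integers(1, 4, n_mut)) % 4]
                    mutated[start:stop] = mask.any(axis=1)
            out = []
            for i, row in enumerate(rows, start):
                out.append(f"@{read_prefix}_{i}\n{row.tobytes().decode()}\n+\n{qual}\n")
            fh.write("".join(out))

    bcs = np.array(library.bcs, dtype=object)
    rois = np.array(library.roi_seqs, dtype=object)
    truth = pd.DataFrame(
        {
            "read_id": [f"{read_prefix}_{i}" for i in range(n_reads)],
            "bc": bcs[clone_idx],
            "roi": rois[roi_id],
            "chimeric": roi_id != library.clone_roi_id[clone_idx],
            "mutated": mutated,
        }
    )
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    if sidecar is not None:
        side = dict(sidecar)
        side.setdefault("sample", sample)
        side.setdefault("n_reads", n_reads)
        side.setdefault("sub_rate", error_model.sub_rate)
        Path(str(path) + ".json").write_text(json.dumps(side, indent=2, default=str))
    return truth


def params_sidecar(params: ProtocolParams, error_model: ErrorModel, seed) -> dict:
    """Reproducibility record for a simulation run."""
    return {
        "protocol": dataclasses.asdict(params),
        "error_model": dataclasses.asdict(error_model),
        "seed": seed,
    }
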