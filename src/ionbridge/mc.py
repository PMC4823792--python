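"""Counterion-bridging Monte Carlo: a minimal lattice-free model of
biphasic, ion-concentration-dependent protein clustering.

The model abstracts membrane-anchored anionic proteins as point particles
in a 2-D periodic box (the membrane plane), each carrying
``sites_per_particle`` unit-negative binding sites (carboxylates).
Divalent cations diffuse in the same plane and may occupy up to
``max_sites_per_ion`` sites, but only while within ``contact_radius_nm``
of the owning particle. The energy has three terms:

``E = (bind_energy + binding_entropy) * n_bound_pairs
   + bridge_energy * sum_ions max(0, distinct_particles - 1)
   + charge_penalty * sum_{neighbour pairs} q_p * q_p'``

* **binding** — ``bind_energy`` (< 0) is the ion-carboxylate contact
  energy; ``binding_entropy`` (> 0) is the free-energy cost of confining a
  free ion to a site, so that a lone bond is only marginally favourable
  and site occupancy is driven by the local free-ion availability, i.e.
  by concentration.
* **bridging** — an ion holding carboxylates of two or more distinct
  particles is an ion bridge and is rewarded per extra particle linked.
* **charge repulsion** — each particle carries the net charge
  ``q_p = 2 * (ion charge shares bound to p) - sites_per_particle``
  (a bridging ion splits its +2 evenly among the particles it holds);
  particle pairs closer than ``repulsion_range_nm`` interact with a
  screened-Coulomb-like contact term ``charge_penalty * q_p * q_p'``.

These three ingredients reproduce the proposed mechanism: with scarce
ions the bare anionic particles (q = -S) repel and stay dispersed; at
intermediate counts bound cations neutralise them and ion bridges
assemble oligomers; an ion excess saturates the sites one-ion-per-site,
overcharges the particles (q > 0), re-establishes the mutual repulsion
and blocks bridge geometry — a biphasic cluster-size curve.

Sampling is Metropolis over particle translations, ion translations and
symmetric bind/unbind toggles (site drawn uniformly, then an ion uniformly
among those within contact range of the owning particle; the candidate set
depends only on positions, which a toggle never changes, so the proposal
is exactly symmetric). Bound ions tether: a translation that would carry a
bound ion out of range of its particles (or vice versa) is rejected as an
infinite-energy move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

#: Reference parameter set for the biphasic demonstration (see
#: ``biphasic_scan``); the rationale is documented in docs/methods.md.
REFERENCE_PARAMS = dict(
    n_particles=24, sites_per_particle=6, box_nm=(20.0, 20.0),
    bridge_energy_kT=-2.25, bind_energy_kT=-1.0, binding_entropy_kT=2.0,
    charge_penalty_kT=0.25, contact_radius_nm=1.2, repulsion_range_nm=2.4,
    particle_step_nm=0.8, ion_step_nm=2.0, max_sites_per_ion=4,
    hard_core_nm=0.0, n_sweeps=800,
)

#: Ion counts spanning the scarce / neutralising / saturating regimes.
REFERENCE_ION_COUNTS = (6, 96, 3000)


@dataclass
class ToyParams:
    n_particles: int = 24
    sites_per_particle: int = 6
    box_nm: tuple = (20.0, 20.0)
    ion_count: int = 72
    bridge_energy_kT: float = -2.25
    bind_energy_kT: float = -1.0
    binding_entropy_kT: float = 2.0
    charge_penalty_kT: float = 0.25
    contact_radius_nm: float = 1.2
    repulsion_range_nm: float = 2.4
    particle_step_nm: float = 0.8
    ion_step_nm: float = 2.0
    max_sites_per_ion: int = 4
    hard_core_nm: float = 0.0
    n_sweeps: int = 800
    seed: int = 0

    def validate(self) -> None:
        if self.n_particles < 1 or self.sites_per_particle < 0 or self.ion_count < 0:
            raise ValueError("counts must be non-negative (>= 1 particle)")
        if not 1 <= self.max_sites_per_ion <= 10:
            raise ValueError("max_sites_per_ion must be in 1..10")
        box = np.asarray(self.box_nm, dtype=float)
        if np.any(box <= 0):
            raise ValueError("box edges must be positive")
        if self.contact_radius_nm <= 0 or self.contact_radius_nm >= box.min() / 2:
            raise ValueError("contact_radius must be in (0, half min box edge)")
        if not 0 < self.repulsion_range_nm < box.min() / 2:
            raise ValueError("repulsion_range must be in (0, half min box edge)")
        for e in (self.bridge_energy_kT, self.bind_energy_kT,
                  self.binding_entropy_kT, self.charge_penalty_kT):
            if not math.isfinite(e):
                raise ValueError("energies must be finite")


class McState:
    """Mutable simulation state with incremental occupancy bookkeeping."""

    def __init__(self, params: ToyParams, rng: np.random.Generator):
        params.validate()
        self.p = params
        self.box = np.asarray(params.box_nm, dtype=float)
        self.particles = rng.uniform(0, self.box, size=(params.n_particles, 2))
        self.ions = rng.uniform(0, self.box, size=(params.ion_count, 2))
        n_sites = params.n_particles * params.sites_per_particle
        self.site_ion = np.full(n_sites, -1, dtype=int)   # site -> ion or -1
        # per-ion particle multiset {particle: n_sites_bound}
        self.ion_particles: list[dict] = [dict() for _ in range(params.ion_count)]
        self.ion_load = np.zeros(params.ion_count, dtype=int)
        # per-particle bound-ion multiset {ion: n_sites}
        self.particle_ions: list[dict] = [dict() for _ in range(params.n_particles)]
        self.bound_ions: set[int] = set()
        self.n_bound = 0
        # per-particle net charge: -S plus +2 shares of bound ions
        self.q = np.full(params.n_particles, -float(params.sites_per_particle))
        self.sweep = 0
        self.energy = self.total_energy()

    # -- geometry ----------------------------------------------------------

    def _dist(self, a, b) -> float:
        d = a - b
        d -= self.box * np.round(d / self.box)
        return float(np.hypot(d[0], d[1]))

    def ions_in_range_of_particles(self, radius: float) -> list[np.ndarray]:
        """Per-particle arrays of ion indices within ``radius`` (periodic),
        from one vectorised particle-ion distance matrix. Valid as long as
        no position moves (i.e. for one toggle phase)."""
        if len(self.ions) == 0:
            return [np.empty(0, dtype=int) for _ in range(len(self.particles))]
        d = self.particles[:, None, :] - self.ions[None, :, :]
        d -= self.box * np.round(d / self.box)
        dist2 = np.einsum("pik,pik->pi", d, d)
        within = dist2 < radius * radius
        return [np.flatnonzero(within[p]) for p in range(len(self.particles))]

    def neighbour_pairs(self) -> list[tuple[int, int]]:
        """Particle pairs within the repulsion range (periodic)."""
        P = len(self.particles)
        d = self.particles[:, None, :] - self.particles[None, :, :]
        d -= self.box * np.round(d / self.box)
        dist2 = np.einsum("pik,pik->pi", d, d)
        rr = self.p.repulsion_range_nm ** 2
        out = []
        for a in range(P):
            for b in range(a + 1, P):
                if dist2[a, b] < rr:
                    out.append((a, b))
        return out

    # -- energy ------------------------------------------------------------

    def _bridge_term(self) -> float:
        e = 0.0
        for ion in self.bound_ions:
            parts = self.ion_particles[ion]
            if len(parts) >= 2:
                e += self.p.bridge_energy_kT * (len(parts) - 1)
        return e

    def _pair_repulsion(self, pairs=None) -> float:
        lam = self.p.charge_penalty_kT
        if lam == 0.0:
            return 0.0
        if pairs is None:
            pairs = self.neighbour_pairs()
        q = self.q
        return lam * sum(q[a] * q[b] for a, b in pairs)

    def particle_pair_energy(self, part: int, pos) -> float:
        """Charge-interaction energy of one particle at ``pos`` with all
        neighbours within range (used for translation Metropolis)."""
        lam = self.p.charge_penalty_kT
        if lam == 0.0:
            return 0.0
        rr = self.p.repulsion_range_nm
        e = 0.0
        for other in range(len(self.particles)):
            if other == part:
                continue
            if self._dist(pos, self.particles[other]) < rr:
                e += lam * self.q[part] * self.q[other]
        return e

    def total_energy(self, pairs=None) -> float:
        per_bond = self.p.bind_energy_kT + self.p.binding_entropy_kT
        return (per_bond * self.n_bound + self._bridge_term()
                + self._pair_repulsion(pairs))

    # -- bookkeeping -------------------------------------------------------

    def _update_shares(self, ion: int, old_k: int, new_k: int) -> None:
        """Re-split the ion's +2 charge when its distinct-particle count
        changes from old_k to new_k."""
        if old_k == new_k:
            return
        for part in self.ion_particles[ion]:
            self.q[part] += 2.0 / new_k - (2.0 / old_k if old_k else 0.0)

    def _bind(self, ion: int, site: int) -> None:
        part = site // self.p.sites_per_particle
        old_k = len(self.ion_particles[ion])
        self.site_ion[site] = ion
        new = part not in self.ion_particles[ion]
        self.ion_particles[ion][part] = self.ion_particles[ion].get(part, 0) + 1
        self.particle_ions[part][ion] = self.particle_ions[part].get(ion, 0) + 1
        self.ion_load[ion] += 1
        self.bound_ions.add(ion)
        self.n_bound += 1
        if new:
            new_k = old_k + 1
            # existing particles lose share, the new one gains its share
            for other in self.ion_particles[ion]:
                if other != part:
                    self.q[other] += 2.0 / new_k - 2.0 / old_k
            self.q[part] += 2.0 / new_k

    def _unbind(self, ion: int, site: int) -> None:
        part = site // self.p.sites_per_particle
        old_k = len(self.ion_particles[ion])
        self.site_ion[site] = -1
        for table, key in ((self.ion_particles[ion], part),
                           (self.particle_ions[part], ion)):
            table[key] -= 1
            if table[key] == 0:
                del table[key]
        self.ion_load[ion] -= 1
        if self.ion_load[ion] == 0:
            self.bound_ions.discard(ion)
        self.n_bound -= 1
        if part not in self.ion_particles[ion]:
            new_k = old_k - 1
            self.q[part] -= 2.0 / old_k
            for other in self.ion_particles[ion]:
                self.q[other] += (2.0 / new_k if new_k else 0.0) - 2.0 / old_k

    # -- cluster readout ---------------------------------------------------

    def cluster_partition(self, contact_rule: str = "bridge",
                          direct_contact_nm: float | None = None):
        """Partition of particles into complexes. ``contact_rule`` is
        ``"bridge"`` (particles share a bound ion) or ``"bridge+contact"``
        (also link particles within ``direct_contact_nm``). Returns a list
        of particle index lists."""
        P = self.p.n_particles
        parent = list(range(P))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for ion in self.bound_ions:
            plist = list(self.ion_particles[ion])
            for q in plist[1:]:
                union(plist[0], q)
        if contact_rule == "bridge+contact":
            if direct_contact_nm is None:
                raise ValueError("direct_contact_nm required for bridge+contact rule")
            for a in range(P):
                for b in range(a + 1, P):
                    if self._dist(self.particles[a], self.particles[b]) < direct_contact_nm:
                        union(a, b)
        elif contact_rule != "bridge":
            raise ValueError(f"unknown contact rule {contact_rule!r}")
        comps: dict[int, list] = {}
        for part in range(P):
            comps.setdefault(find(part), []).append(part)
        return list(comps.values())


@dataclass
class McTrace:
    params: ToyParams
    sweeps: np.ndarray
    energy: np.ndarray
    n_bound: np.ndarray
    largest_cluster: np.ndarray
    mean_cluster: np.ndarray
    acceptance: dict
    final_state: McState
    energy_bookkeeping_error: float

    def equilibration_drift(self) -> float:
        """Mean cluster-size drift between the 3rd and 4th quarters of the
        run, in units of the pooled s.e.m. (heuristic flatness check)."""
        n = len(self.mean_cluster)
        a = self.mean_cluster[n // 2: 3 * n // 4]
        b = self.mean_cluster[3 * n // 4:]
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        return float(abs(b.mean() - a.mean()) / se) if se > 0 else 0.0


def run_mc(params: ToyParams, record_every: int = 1,
           initial_state: McState | None = None) -> McTrace:
    """Metropolis run; returns per-sweep observables and the final state.

    Per sweep: one attempted translation per particle and per ion, plus
    ``4 * n_sites`` bind/unbind toggles. The running energy is updated
    incrementally and checked against a full recomputation at the end (the
    bookkeeping error is reported and must be ~1e-9 kT)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    if initial_state is None:
        st = McState(params, rng)
    else:
        st = initial_state
        st.energy = st.total_energy()
    P, S, I = params.n_particles, params.sites_per_particle, params.ion_count
    n_sites = P * S
    n_toggles = 4 * n_sites if I else 0
    r = params.contact_radius_nm
    att = {"particle": 0, "ion": 0, "toggle": 0}
    acc = {"particle": 0, "ion": 0, "toggle": 0}

    rows = []
    for sweep in range(params.n_sweeps):
        # particle translations (Metropolis on the charge-pair energy,
        # gated by bound-ion tethers and the optional hard core)
        for part in rng.permutation(P):
            att["particle"] += 1
            step = rng.uniform(-params.particle_step_nm, params.particle_step_nm, 2)
            if params.particle_step_nm == 0.0:
                acc["particle"] += 1
                continue
            new = (st.particles[part] + step) % st.box
            ok = all(st._dist(new, st.ions[i]) < r
                     for i in st.particle_ions[part])
            if ok and params.hard_core_nm > 0:
                ok = all(st._dist(new, st.particles[o]) >= params.hard_core_nm
                         for o in range(P) if o != part)
            if not ok:
                continue
            de = (st.particle_pair_energy(part, new)
                  - st.particle_pair_energy(part, st.particles[part]))
            if de <= 0 or rng.uniform() < math.exp(-de):
                st.particles[part] = new
                st.energy += de
                acc["particle"] += 1
        # ion translations: unbound ions are unconstrained and move in one
        # vectorised step; bound ions must stay within range
        if I:
            att["ion"] += I
            steps = rng.uniform(-params.ion_step_nm, params.ion_step_nm, (I, 2))
            free_mask = np.ones(I, dtype=bool)
            for ion in st.bound_ions:
                free_mask[ion] = False
            st.ions[free_mask] = (st.ions[free_mask] + steps[free_mask]) % st.box
            acc["ion"] += int(free_mask.sum())
            for ion in sorted(st.bound_ions):
                new = (st.ions[ion] + steps[ion]) % st.box
                if all(st._dist(new, st.particles[q]) < r
                       for q in st.ion_particles[ion]):
                    st.ions[ion] = new
                    acc["ion"] += 1
        # bind/unbind toggles: positions are frozen in this phase, so the
        # candidate sets and the neighbour-pair list are computed once
        if I:
            cand_by_particle = st.ions_in_range_of_particles(r)
            pairs = st.neighbour_pairs()
        for _ in range(n_toggles):
            att["toggle"] += 1
            site = int(rng.integers(n_sites))
            part = site // S
            cand = cand_by_particle[part]
            if len(cand) == 0:
                continue
            ion = int(cand[int(rng.integers(len(cand)))])
            holder = st.site_ion[site]
            if holder == ion:
                e0 = st.energy
                st._unbind(ion, site)
                e1 = st.total_energy(pairs)
                if e1 - e0 <= 0 or rng.uniform() < math.exp(-(e1 - e0)):
                    st.energy = e1
                    acc["toggle"] += 1
                else:
                    st._bind(ion, site)
            elif holder == -1 and st.ion_load[ion] < params.max_sites_per_ion:
                # occupied-by-other or capacity-full proposals are rejected
                # above without paying the energy recompute
                e0 = st.energy
                st._bind(ion, site)
                e1 = st.total_energy(pairs)
                if e1 - e0 <= 0 or rng.uniform() < math.exp(-(e1 - e0)):
                    st.energy = e1
                    acc["toggle"] += 1
                else:
                    st._unbind(ion, site)
        st.sweep = sweep + 1
        if sweep % record_every == 0:
            comps = st.cluster_partition()
            sizes = [len(c) for c in comps]
            rows.append((sweep, st.energy, st.n_bound, max(sizes),
                         P / len(comps)))

    book_err = abs(st.energy - st.total_energy())
    arr = np.array(rows)
    acceptance = {k: (acc[k] / att[k] if att[k] else float("nan")) for k in att}
    return McTrace(params, arr[:, 0].astype(int), arr[:, 1], arr[:, 2].astype(int),
                   arr[:, 3].astype(int), arr[:, 4], acceptance, st, book_err)


def cluster_partition(state: McState, contact_rule: str = "bridge",
                      direct_contact_nm: float | None = None):
    """Module-level convenience over :meth:`McState.cluster_partition`;
    returns ``(partition, sorted_sizes)``."""
    parts = state.cluster_partition(contact_rule, direct_contact_nm)
    return parts, sorted((len(c) for c in parts), reverse=True)


def biphasic_scan(base_params: ToyParams | dict | None = None,
                  ion_counts=REFERENCE_ION_COUNTS, n_seeds: int = 4,
                  seed: int = 0, equil_fraction: float = 0.5):
    """Mean cluster metrics vs ion count, averaged over independent seeds.

    For each ion count, ``n_seeds`` runs are performed (seeds derived from
    ``seed``); observables are averaged over the trailing
    ``equil_fraction`` of sweeps, then mean +/- SE across seeds. Returns a
    list of dicts with keys ``ion_count, mean_cluster, mean_cluster_se,
    largest_cluster, largest_cluster_se, per_seed_*, drift_z``.
    """
    if len(ion_counts) < 3:
        raise ValueError("need ion counts spanning low/mid/high")
    if base_params is None:
        base = dict(REFERENCE_PARAMS)
    elif isinstance(base_params, ToyParams):
        base = asdict(base_params)
    else:
        base = dict(base_params)
    base.pop("ion_count", None)
    base.pop("seed", None)
    out = []
    for count in ion_counts:
        means, larges, drifts = [], [], []
        for s in range(n_seeds):
            p = ToyParams(**base, ion_count=int(count),
                          seed=(seed * 10007 + 97 * s + count) % (2**31 - 1))
            tr = run_mc(p, record_every=5)
            n = len(tr.mean_cluster)
            tail = slice(int((1 - equil_fraction) * n), n)
            means.append(float(tr.mean_cluster[tail].mean()))
            larges.append(float(tr.largest_cluster[tail].mean()))
            drifts.append(tr.equilibration_drift())
        means = np.array(means)
        larges = np.array(larges)
        out.append({
            "ion_count": int(count),
            "mean_cluster": float(means.mean()),
            "mean_cluster_se": float(means.std(ddof=1) / np.sqrt(n_seeds)) if n_seeds > 1 else 0.0,
            "largest_cluster": float(larges.mean()),
            "largest_cluster_se": float(larges.std(ddof=1) / np.sqrt(n_seeds)) if n_seeds > 1 else 0.0,
            "per_seed_mean_cluster": means.tolist(),
            "per_seed_largest_cluster": larges.tolist(),
            "drift_z": float(np.mean(drifts)),
        })
    return out
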