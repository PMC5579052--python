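"""Cluster sets: the molecular input of a quantum cluster equilibrium run.

A cluster set bundles one monomer definition with a list of clusters, each
described by its composition (number of monomers, hydronium/hydroxide
counts), adiabatic interaction energy relative to the separated monomers,
harmonic frequencies, rotational constants, symmetry number and volume.
Net-neutral ion-pair clusters (one H3O+ and one OH- separated by neutral
water "buttresses") carry the autoionization signal; everything else is
conventional neutral hydrogen-bonded water.

Canonical internal units: kJ/mol, cm^-1, GHz, Å^3, amu, K, Pa.  Unit
conversion happens only at the I/O boundary (``load_cluster_set``).

On-disk format: one directory per set with a TOML manifest
(``clusterset.toml``) listing monomer properties and per-cluster entries;
frequencies live in sidecar files (one wavenumber per line) and optional
geometries in standard XYZ.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import HARTREE_TO_KJMOL, KCALMOL_TO_KJMOL, WATER_MOLAR_MASS
from .xyz import Atom, read_xyz, write_xyz

__all__ = [
    "Monomer",
    "Cluster",
    "ClusterSet",
    "ClusterSetError",
    "load_cluster_set",
    "write_cluster_set",
    "validate_cluster_set",
    "synthetic_cluster_set",
    "toy_water_set",
]

#: accepted energy unit tags in manifests → factor to kJ/mol
ENERGY_UNITS = {
    "kJ/mol": 1.0,
    "kj/mol": 1.0,
    "hartree": HARTREE_TO_KJMOL,
    "kcal/mol": KCALMOL_TO_KJMOL,
}

MANIFEST_NAME = "clusterset.toml"


class ClusterSetError(ValueError):
    """Raised when a cluster set fails validation at the I/O boundary."""


@dataclass(frozen=True)
class Monomer:
    """The repeat unit all clusters are built from (H2O in the water sets)."""

    label: str
    mass: float          # amu
    molar_mass: float    # g/mol (numerically equal to mass for one species)

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"monomer mass must be positive, got {self.mass}")
        if not math.isclose(self.mass, self.molar_mass, rel_tol=1e-6):
            raise ValueError("monomer mass (amu) and molar mass (g/mol) must agree numerically")


@dataclass(frozen=True)
class Cluster:
    """One cluster species: composition, energetics, spectroscopy, volume."""

    label: str
    n_monomers: int
    interaction_energy: float           # kJ/mol, relative to separated monomers
    frequencies: tuple[float, ...]      # cm^-1, harmonic, all > 0 for minima
    rotational_constants: tuple[float, float, float]  # GHz
    volume: float                       # Å^3
    symmetry_number: int = 1
    n_hydronium: int = 0
    n_hydroxide: int = 0
    geometry: tuple[Atom, ...] | None = None

    @property
    def is_ion_pair(self) -> bool:
        return self.n_hydronium > 0 or self.n_hydroxide > 0

    def expected_mode_count(self) -> int:
        # nonlinear cluster of n rigid monomers with 3 atoms each: 9n - 6
        return 9 * self.n_monomers - 6


@dataclass
class ClusterSet:
    """A validated collection of clusters sharing one monomer definition."""

    monomer: Monomer
    clusters: list[Cluster]
    name: str = "cluster-set"

    def require_valid(self) -> "ClusterSet":
        """Raise :class:`ClusterSetError` unless the set passes validation."""
        diagnostics = validate_cluster_set(self)
        if diagnostics:
            raise ClusterSetError(
                f"invalid cluster set {self.name!r}:\n  " + "\n  ".join(diagnostics)
            )
        return self

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.clusters]

    @property
    def ion_pair_labels(self) -> list[str]:
        return [c.label for c in self.clusters if c.is_ion_pair]

    def get(self, label: str) -> Cluster:
        for c in self.clusters:
            if c.label == label:
                return c
        raise KeyError(label)

    def with_clusters(self, clusters: list[Cluster], name: str | None = None) -> "ClusterSet":
        return ClusterSet(self.monomer, clusters, name or self.name)


def _validate_cluster(c: Cluster) -> list[str]:
    out = []
    if c.n_monomers < 1:
        out.append(f"{c.label}: n_monomers must be >= 1")
    if c.n_hydronium != c.n_hydroxide:
        out.append(
            f"{c.label}: charge imbalance (n_hydronium={c.n_hydronium}, "
            f"n_hydroxide={c.n_hydroxide}); clusters must be net-neutral ion pairs"
        )
    if min(c.n_hydronium, c.n_hydroxide) < 0:
        out.append(f"{c.label}: negative ion count")
    neg = [f for f in c.frequencies if f <= 0]
    if neg:
        out.append(
            f"{c.label}: imaginary mode ({neg[0]} cm^-1); minima must have all-positive frequencies"
        )
    nmodes = c.expected_mode_count()
    if len(c.frequencies) != nmodes:
        out.append(f"{c.label}: expected {nmodes} modes for n={c.n_monomers}, got {len(c.frequencies)}")
    if len(c.rotational_constants) != 3 or any(b <= 0 for b in c.rotational_constants):
        out.append(f"{c.label}: needs 3 positive rotational constants (nonlinear top); "
                   "atomic/linear species are not supported")
    if c.symmetry_number < 1:
        out.append(f"{c.label}: symmetry number must be >= 1")
    if c.volume <= 0:
        out.append(f"{c.label}: volume must be positive")
    return out


def validate_cluster_set(cs: ClusterSet) -> list[str]:
    """Return a list of human-readable diagnostics; empty iff the set is valid."""
    out: list[str] = []
    labels = [c.label for c in cs.clusters]
    dup = {l for l in labels if labels.count(l) > 1}
    if dup:
        out.append(f"duplicate labels: {sorted(dup)}")
    monomers = [c for c in cs.clusters if c.n_monomers == 1]
    if len(monomers) != 1:
        out.append(f"exactly one monomer cluster (n=1) required, found {len(monomers)}")
    else:
        m = monomers[0]
        if m.interaction_energy != 0.0:
            out.append(f"{m.label}: monomer interaction energy must be 0, got {m.interaction_energy}")
        if cs.clusters[0].n_monomers != 1:
            out.append("the monomer cluster must be the first entry")
    for c in cs.clusters:
        out.extend(_validate_cluster(c))
    return out


# ----------------------------------------------------------------------
# manifest I/O
# ----------------------------------------------------------------------

def load_cluster_set(path: str | Path) -> ClusterSet:
    """Load a cluster set from a directory (or manifest file) on disk.

    Energies may be tagged ``hartree``, ``kJ/mol`` or ``kcal/mol`` and are
    converted to kJ/mol; all other quantities must already be in canonical
    units (cm^-1, GHz, Å^3, amu).
    """
    path = Path(path)
    manifest = path / MANIFEST_NAME if path.is_dir() else path
    root = manifest.parent
    with open(manifest, "rb") as fh:
        doc = tomllib.load(fh)

    try:
        mdoc = doc["monomer"]
        monomer = Monomer(mdoc.get("label", "monomer"), float(mdoc["mass"]),
                          float(mdoc.get("molar_mass", mdoc["mass"])))
    except KeyError as exc:
        raise ClusterSetError(f"{manifest}: missing monomer entry ({exc})") from exc

    clusters = []
    for cdoc in doc.get("clusters", []):
        unit = cdoc.get("energy_unit", "kJ/mol")
        if unit not in ENERGY_UNITS:
            raise ClusterSetError(
                f"{manifest}: unknown energy unit tag {unit!r} for {cdoc.get('label')!r}; "
                f"accepted: {sorted(set(ENERGY_UNITS))}"
            )
        energy = float(cdoc["energy"]) * ENERGY_UNITS[unit]
        freq_file = root / cdoc["frequencies"]
        frequencies = tuple(
            float(ln) for ln in freq_file.read_text().split() if ln.strip()
        )
        geometry = None
        if "geometry" in cdoc:
            geometry = tuple(read_xyz(root / cdoc["geometry"]))
        clusters.append(Cluster(
            label=str(cdoc["label"]),
            n_monomers=int(cdoc["n_monomers"]),
            n_hydronium=int(cdoc.get("n_hydronium", 0)),
            n_hydroxide=int(cdoc.get("n_hydroxide", 0)),
            interaction_energy=energy,
            frequencies=frequencies,
            rotational_constants=tuple(float(b) for b in cdoc["rotational_constants"]),
            symmetry_number=int(cdoc.get("sigma", 1)),
            volume=float(cdoc["volume"]),
            geometry=geometry,
        ))
    return ClusterSet(monomer, clusters, name=doc.get("name", path.stem)).require_valid()


def _fmt(x: float) -> str:
    return repr(float(x))


def write_cluster_set(cs: ClusterSet, path: str | Path) -> Path:
    """Write a cluster set as a manifest directory; returns the manifest path.

    Floats are written with full precision so that load(write(cs)) round-trips
    every field exactly.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    lines = [f'name = "{cs.name}"', "", "[monomer]",
             f'label = "{cs.monomer.label}"',
             f"mass = {_fmt(cs.monomer.mass)}",
             f"molar_mass = {_fmt(cs.monomer.molar_mass)}"]
    for c in cs.clusters:
        freq_name = f"{c.label}.freq"
        (root / freq_name).write_text("\n".join(_fmt(f) for f in c.frequencies) + "\n")
        lines += ["", "[[clusters]]",
                  f'label = "{c.label}"',
                  f"n_monomers = {c.n_monomers}",
                  f"n_hydronium = {c.n_hydronium}",
                  f"n_hydroxide = {c.n_hydroxide}",
                  f"energy = {_fmt(c.interaction_energy)}",
                  'energy_unit = "kJ/mol"',
                  f"volume = {_fmt(c.volume)}",
                  f"sigma = {c.symmetry_number}",
                  f'frequencies = "{freq_name}"',
                  "rotational_constants = ["
                  + ", ".join(_fmt(b) for b in c.rotational_constants) + "]"]
        if c.geometry is not None:
            xyz_name = f"{c.label}.xyz"
            write_xyz(root / xyz_name, list(c.geometry), comment=c.label)
            lines.append(f'geometry = "{xyz_name}"')
    manifest = root / MANIFEST_NAME
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


# ----------------------------------------------------------------------
# synthetic sets
# ----------------------------------------------------------------------

#: gas-phase rotational constants of the water monomer, GHz
WATER_ROT_GHZ = (835.8, 435.1, 278.4)
#: intramolecular normal modes of the water monomer, cm^-1 (bend, sym, asym)
WATER_MODES = (1594.7, 3657.1, 3755.9)
#: van der Waals volume of a water molecule, Å^3 (Bondi-sphere union scale)
WATER_VDW_VOLUME = 20.0

#: default energetic penalty of an ion-pair cluster over its neutral isomer,
#: kJ/mol.  Chosen so that the Boltzmann-suppressed ion-pair populations land
#: in the physically relevant 1e-7 mol/L range at ambient temperature
#: (pK_W ~ 12-15), the regime the solver must resolve.
DEFAULT_IP_DESTABILIZATION = 40.0

#: hydrogen-bond energy scale, kJ/mol per bond (drawn near this mean)
HB_ENERGY = 25.0


def _intramolecular_modes(rng: np.random.Generator, n: int) -> list[float]:
    """3n intramolecular modes: jittered copies of the monomer's bend/stretches."""
    out = []
    for _ in range(n):
        bend, sym, asym = WATER_MODES
        out += [bend + rng.normal(0.0, 25.0),
                sym + rng.normal(-60.0, 60.0),   # bonded OH red-shift
                asym + rng.normal(-30.0, 40.0)]
    return out


def _intermolecular_modes(rng: np.random.Generator, n: int) -> list[float]:
    """6n-6 low-frequency intermolecular modes (translations + librations)."""
    k = 6 * n - 6
    k_trans = k // 2
    return list(rng.uniform(40.0, 280.0, size=k_trans)) + \
        list(rng.uniform(300.0, 900.0, size=k - k_trans))


def _make_cluster(rng: np.random.Generator, label: str, n: int, energy: float,
                  n_ion: int = 0) -> Cluster:
    freqs = sorted(_intermolecular_modes(rng, n) + _intramolecular_modes(rng, n))
    scale = n ** (-5.0 / 3.0)
    rot = sorted((b * scale * rng.uniform(0.9, 1.1) for b in WATER_ROT_GHZ), reverse=True)
    volume = n * WATER_VDW_VOLUME * (1.0 + rng.normal(0.0, 0.03))
    return Cluster(
        label=label, n_monomers=n, interaction_energy=energy,
        frequencies=tuple(max(f, 30.0) for f in freqs),
        rotational_constants=tuple(rot), volume=volume,
        n_hydronium=n_ion, n_hydroxide=n_ion,
    )


def synthetic_cluster_set(seed: int = 0, max_size: int = 10,
                          ip_destabilization: float = DEFAULT_IP_DESTABILIZATION,
                          ) -> ClusterSet:
    """Generate a deterministic water-like cluster set.

    Emulates the canonical 18-cluster water topology: a monomer, a dimer,
    cyclic (Grotthus-ordered ring, n hydrogen bonds) clusters for n = 3..
    ``max_size`` plus open-chain (n-1 bonds) isomers for n = 3, 4, and for
    every n >= 5 one net-neutral ion-pair isomer whose interaction energy is
    the ring's plus ``ip_destabilization``.  With ``max_size=10`` this yields
    exactly 18 clusters.

    Pure function of its arguments: the same ``(seed, max_size)`` always
    yields the same set, and ``ip_destabilization`` enters only additively in
    the ion-pair energies (so two sets differing only in the destabilization
    are identical cluster for cluster except for those energies).
    """
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    if ip_destabilization < 0:
        raise ValueError("ip_destabilization must be >= 0")
    rng = np.random.default_rng(seed)
    monomer = Monomer("W1", WATER_MOLAR_MASS, WATER_MOLAR_MASS)

    clusters = [Cluster(
        label="W1", n_monomers=1, interaction_energy=0.0,
        frequencies=WATER_MODES, rotational_constants=WATER_ROT_GHZ,
        volume=WATER_VDW_VOLUME, symmetry_number=1,
    )]
    ring_energy: dict[int, float] = {}
    # dimer: single hydrogen bond
    clusters.append(_make_cluster(rng, "W2", 2, -rng.normal(HB_ENERGY, 1.0)))
    for n in range(3, max_size + 1):
        e_ring = -n * rng.normal(HB_ENERGY, 1.0)
        ring_energy[n] = e_ring
        clusters.append(_make_cluster(rng, f"W{n}c", n, e_ring))
        if n <= 4:  # open-chain isomers of the small rings (n-1 bonds)
            clusters.append(_make_cluster(rng, f"W{n}u", n, -(n - 1) * rng.normal(HB_ENERGY, 1.0)))
    for n in range(5, max_size + 1):
        ip = _make_cluster(rng, f"W{n}ip", n, ring_energy[n] + ip_destabilization, n_ion=1)
        clusters.append(ip)
    return ClusterSet(monomer, clusters, name=f"synthetic-water-{max_size}-seed{seed}")


def toy_water_set() -> ClusterSet:
    """A tiny illustrative water set: monomer, cyclic trimer, cyclic pentamer
    and one ion-pair pentamer.

    Hand-curated, physically plausible values on the scale of published
    DFT water-cluster data; packaged for examples and fast tests, not a
    transcription of any quantum-chemistry dataset.
    """
    monomer = Monomer("W1", WATER_MOLAR_MASS, WATER_MOLAR_MASS)
    w1 = Cluster("W1", 1, 0.0, WATER_MODES, WATER_ROT_GHZ, WATER_VDW_VOLUME,
                 symmetry_number=1)
    trimer_freqs = tuple(sorted(
        [170.0, 185.0, 210.0, 330.0, 420.0, 450.0, 560.0, 650.0, 720.0,
         810.0, 850.0, 920.0,
         1608.0, 1615.0, 1622.0, 3420.0, 3450.0, 3510.0, 3720.0, 3725.0, 3730.0]))
    w3c = Cluster("W3c", 3, -66.0, trimer_freqs, (6.9, 6.7, 3.5), 61.0,
                  symmetry_number=3)
    pent_inter = [30.0, 45.0, 60.0, 78.0, 95.0, 120.0, 150.0, 175.0, 200.0,
                  225.0, 250.0, 290.0, 330.0, 370.0, 410.0, 450.0, 500.0,
                  550.0, 610.0, 670.0, 730.0, 790.0, 860.0, 940.0]
    pent_intra = [1602.0, 1607.0, 1612.0, 1617.0, 1622.0,
                  3320.0, 3360.0, 3400.0, 3440.0, 3480.0,
                  3715.0, 3718.0, 3721.0, 3724.0, 3727.0]
    w5c = Cluster("W5c", 5, -130.0, tuple(sorted(pent_inter + pent_intra)),
                  (1.85, 1.78, 0.95), 102.0, symmetry_number=5)
    ip_freqs = tuple(sorted([f * 0.98 for f in pent_inter]
                            + [f * 0.99 for f in pent_intra]))
    w5ip = Cluster("W5ip", 5, -92.0, ip_freqs, (1.9, 1.8, 1.0), 103.0,
                   n_hydronium=1, n_hydroxide=1)
    return ClusterSet(monomer, [w1, w3c, w5c, w5ip], name="toy-water")
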