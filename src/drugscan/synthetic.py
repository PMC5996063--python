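"""Synthetic pharmacogenomic corpora with a planted, recoverable signal.

The generator emulates the *shape* of a public cell-line screening corpus —
a sparse somatic-mutation table over a gene panel, a drug registry with
valid SMILES, and a dense cell-line × drug ln(IC50) assay matrix — without
any of its pharmacology.  The planted response model is additive in
ln(IC50):

    y(cell, drug) = baseline(drug)
                    + sum_d effect_d * [cell carries driver d] * [drug carries bit b_d]
                    + Normal(0, noise_sd)

where each driver d is a (gene, position) vocabulary key enriched in some
cancer types and b_d is a molecular-fingerprint bit shared by a subset of
drugs.  Because the signal is an explicit function of the same fingerprints
the models consume, an oracle that knows the truth achieves R^2 = 1 at zero
noise, and Var(signal) / (Var(signal) + noise_sd^2) is the analytic ceiling
for any predictor at a given noise level.

Default sizes (5 cancer types x 40 lines, 2,000-key vocabulary, 30 drugs,
10 drivers, noise_sd 0.5) are chosen so a full train-and-evaluate cycle
runs in minutes on one CPU while keeping the corpus shape realistic:
mutation profiles are sparse (~1% of positions), drug baselines dominate
the variance as they do in real screens, and driver-linked effects are on
the scale of a strong targeted-therapy response (1.5-3 ln units).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .curation import assemble_instances, filter_cancer_types, filter_gdsc_drugs
from .exceptions import ConfigurationError, MoleculeParseError
from .fingerprints import GenomicFingerprinter, MolecularFingerprinter

# drug-like template structures (aspirin, caffeine, ibuprofen, naproxen,
# acetaminophen, benzocaine, diazepam, diphenhydramine, chlorpromazine,
# kinase-inhibitor and SERM scaffolds...); variants are built by prepending
# methylene units, which keeps the SMILES valid for templates that start
# with an atom symbol
TEMPLATE_SMILES = (
    "CC(=O)Oc1ccccc1C(=O)O",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",
    "CC(=O)Nc1ccc(O)cc1",
    "CCOC(=O)c1ccc(N)cc1",
    "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",
    "CN(C)CCOC(c1ccccc1)c1ccccc1",
    "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21",
    "Cc1ccc(cc1Nc1nccc(n1)-c1cccnc1)NC(=O)c1ccc(cc1)CN1CCN(C)CC1",
    "COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1",
    "COCCOc1cc2ncnc(Nc3cccc(C#C)c3)c2cc1OCCOC",
    "CC/C(=C(\\c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1",
    "CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1",
    "CN(C)CCCN1c2ccccc2CCc2ccccc21",
    "Cc1ccccc1NC(=O)c1ccccc1",
)


@dataclass(frozen=True)
class SyntheticPanel:
    """A generated cell-line panel and its mutation table."""

    cell_lines: pd.DataFrame      # cell_line_id, cancer_type, mutation_count
    mutations: pd.DataFrame       # cell_line_id, cancer_type, gene, position, ref, alt
    vocab_keys: tuple             # all (gene, position) keys in the feature space
    drivers: tuple                # the planted driver keys
    driver_types: dict            # driver key -> tuple of enriched cancer types


def generate_panel(n_types: int = 5, lines_per_type: int = 40, vocab_size: int = 2000,
                   mutation_rate: float = 0.01, seed: int = 0, n_drivers: int = 10,
                   driver_carrier_rate: float = 0.35) -> SyntheticPanel:
    """Generate cell lines with sparse mutation profiles and enriched drivers.

    Each line mutates every vocabulary key independently at ``mutation_rate``;
    driver keys are additionally carried at ``driver_carrier_rate`` by lines
    of the driver's enriched cancer types.
    """
    if min(n_types, lines_per_type, vocab_size) < 1:
        raise ConfigurationError("all panel counts must be >= 1")
    if not 0 <= mutation_rate < 1:
        raise ConfigurationError(f"mutation_rate must be in [0, 1), got {mutation_rate}")
    if vocab_size < n_drivers:
        raise ConfigurationError(
            f"vocab_size {vocab_size} cannot host {n_drivers} drivers"
        )
    rng = np.random.default_rng(seed)
    positions_per_gene = 40
    keys = tuple(
        (f"G{i // positions_per_gene:04d}", i % positions_per_gene + 1)
        for i in range(vocab_size)
    )
    types = [f"TYPE{t:02d}" for t in range(n_types)]
    driver_idx = rng.choice(vocab_size, size=n_drivers, replace=False)
    drivers = tuple(keys[i] for i in sorted(driver_idx))
    driver_types = {}
    for d in drivers:
        mask = rng.random(n_types) < 0.5
        if not mask.any():
            mask[rng.integers(n_types)] = True
        driver_types[d] = tuple(t for t, m in zip(types, mask) if m)

    rows, cl_rows = [], []
    for t in types:
        for i in range(lines_per_type):
            cl = f"CL_{t}_{i:03d}"
            mutated = set(np.flatnonzero(rng.random(vocab_size) < mutation_rate))
            for j, d in zip(sorted(driver_idx), drivers):
                if t in driver_types[d] and rng.random() < driver_carrier_rate:
                    mutated.add(j)
            for j in sorted(mutated):
                gene, pos = keys[j]
                rows.append((cl, t, gene, pos, "A", "T"))
            cl_rows.append((cl, t, len(mutated)))
    mutations = pd.DataFrame(rows, columns=["cell_line_id", "cancer_type", "gene",
                                            "position", "ref", "alt"])
    cell_lines = pd.DataFrame(cl_rows, columns=["cell_line_id", "cancer_type",
                                                "mutation_count"])
    return SyntheticPanel(cell_lines=cell_lines, mutations=mutations, vocab_keys=keys,
                          drivers=drivers, driver_types=driver_types)


def generate_drugs(n_drugs: int = 30, templates=TEMPLATE_SMILES, seed: int = 0,
                   oncology_fraction: float = 0.3, indication_types=()) -> pd.DataFrame:
    """Build a drug registry of validated template variants.

    Variants are produced by prepending methylene units to the template
    SMILES; every structure is parsed and annotated with its molecular
    weight.  Oncology drugs get 1-2 approved indications drawn from
    ``indication_types`` (';'-joined in the table).
    """
    templates = list(templates)
    if n_drugs == 0:
        return pd.DataFrame(columns=["drug_id", "name", "smiles", "molecular_weight",
                                     "compound_registered", "oncology_flag",
                                     "approved_indications"])
    for t in templates:
        if Chem.MolFromSmiles(t) is None:
            raise MoleculeParseError(t, f"invalid template SMILES: {t!r}")
    rng = np.random.default_rng(seed)
    indication_types = list(indication_types)
    rows = []
    for i in range(n_drugs):
        smiles = "C" * (i // len(templates)) + templates[i % len(templates)]
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # pragma: no cover - template scheme guarantees validity
            raise MoleculeParseError(smiles)
        oncology = bool(rng.random() < oncology_fraction)
        indications = ""
        if oncology and indication_types:
            k = int(rng.integers(1, min(2, len(indication_types)) + 1))
            chosen = rng.choice(indication_types, size=k, replace=False)
            indications = ";".join(sorted(chosen))
        rows.append({
            "drug_id": f"DRUG{i:03d}",
            "name": f"compound-{i:03d}",
            "smiles": smiles,
            "molecular_weight": float(Descriptors.MolWt(mol)),
            "compound_registered": True,
            "oncology_flag": oncology,
            "approved_indications": indications,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticTruth:
    """The planted response model.

    ``effects`` maps (driver key, fingerprint bit) to an additive ln(IC50)
    shift applied when the cell carries the driver AND the drug carries the
    bit; ``drug_target_bits`` records, per drug, which of those bits its
    fingerprint actually sets.
    """

    drivers: tuple                      # (gene, position) keys
    driver_bits: dict                   # driver key -> molecular fp bit index
    drug_target_bits: dict              # drug_id -> tuple of carried bit indices
    baselines: dict                     # drug_id -> mean ln(IC50)
    effects: dict                       # (driver key, bit) -> shift
    noise_sd: float
    seed: int

    def to_json(self, path):
        payload = {
            "drivers": [list(d) for d in self.drivers],
            "driver_bits": {f"{g}:{p}": int(b) for (g, p), b in self.driver_bits.items()},
            "drug_target_bits": {k: list(map(int, v)) for k, v in self.drug_target_bits.items()},
            "baselines": self.baselines,
            "effects": {f"{g}:{p}|{b}": e for ((g, p), b), e in self.effects.items()},
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            raw = json.load(fh)

        def key(s):
            g, p = s.rsplit(":", 1)
            return (g, int(p))

        return cls(
            drivers=tuple(tuple([g, int(p)]) for g, p in raw["drivers"]),
            driver_bits={key(k): v for k, v in raw["driver_bits"].items()},
            drug_target_bits={k: tuple(v) for k, v in raw["drug_target_bits"].items()},
            baselines=raw["baselines"],
            effects={(key(k.split("|")[0]), int(k.split("|")[1])): v
                     for k, v in raw["effects"].items()},
            noise_sd=float(raw["noise_sd"]),
            seed=int(raw["seed"]),
        )


def make_truth(panel: SyntheticPanel, drugs: pd.DataFrame, drug_fps: np.ndarray,
               noise_sd: float = 0.5, seed: int = 0,
               effect_range=(1.5, 3.0), baseline_mean: float = 1.0,
               baseline_sd: float = 2.0) -> SyntheticTruth:
    """Plant one fingerprint-bit target per driver and draw effect sizes.

    Target bits are chosen among molecular-fingerprint columns set in 20-80%
    of the drugs, so every interaction differentiates the library.  Effects
    are sensitising (negative), uniform in ``effect_range`` ln units.
    """
    rng = np.random.default_rng(seed)
    prevalence = drug_fps.mean(axis=0)
    candidates = np.flatnonzero((prevalence >= 0.2) & (prevalence <= 0.8))
    if len(candidates) < len(panel.drivers):
        raise ConfigurationError("not enough variable fingerprint bits for the drivers")
    bits = rng.choice(candidates, size=len(panel.drivers), replace=False)
    driver_bits = {d: int(b) for d, b in zip(panel.drivers, bits)}
    effects = {
        (d, int(b)): -float(rng.uniform(*effect_range)) for d, b in driver_bits.items()
    }
    drug_ids = drugs["drug_id"].tolist()
    drug_target_bits = {
        did: tuple(int(b) for b in sorted(driver_bits.values()) if drug_fps[i, b])
        for i, did in enumerate(drug_ids)
    }
    baselines = {did: float(rng.normal(baseline_mean, baseline_sd)) for did in drug_ids}
    return SyntheticTruth(drivers=panel.drivers, driver_bits=driver_bits,
                          drug_target_bits=drug_target_bits, baselines=baselines,
                          effects=effects, noise_sd=float(noise_sd), seed=int(seed))


def _signal_matrix(panel: SyntheticPanel, drugs: pd.DataFrame,
                   truth: SyntheticTruth) -> pd.DataFrame:
    """Noise-free ln(IC50) for every (cell line, drug) pair."""
    carried = {
        cl: set(zip(grp["gene"], grp["position"]))
        for cl, grp in panel.mutations.groupby("cell_line_id")
    }
    cells = panel.cell_lines["cell_line_id"].tolist()
    drug_ids = drugs["drug_id"].tolist()
    out = np.zeros((len(cells), len(drug_ids)))
    for j, did in enumerate(drug_ids):
        bits = set(truth.drug_target_bits.get(did, ()))
        base = truth.baselines[did]
        shifts = [(drv, eff) for (drv, bit), eff in truth.effects.items() if bit in bits]
        for i, cl in enumerate(cells):
            mut = carried.get(cl, set())
            out[i, j] = base + sum(e for d, e in shifts if d in mut)
    return pd.DataFrame(out, index=cells, columns=drug_ids)


def simulate_responses(panel: SyntheticPanel, drugs: pd.DataFrame,
                       truth: SyntheticTruth) -> pd.DataFrame:
    """Assay table: planted signal plus Normal(0, noise_sd) noise."""
    signal = _signal_matrix(panel, drugs, truth)
    rng = np.random.default_rng(truth.seed)
    noisy = signal.values + rng.normal(0.0, truth.noise_sd, size=signal.shape)
    long = pd.DataFrame({
        "cell_line_id": np.repeat(signal.index.values, signal.shape[1]),
        "drug_id": np.tile(signal.columns.values, signal.shape[0]),
        "ln_ic50": noisy.ravel(),
    })
    return long


def true_signal(panel: SyntheticPanel, drugs: pd.DataFrame, truth: SyntheticTruth,
                instances: pd.DataFrame) -> np.ndarray:
    """Oracle (noise-free) predictions aligned with an instance table."""
    signal = _signal_matrix(panel, drugs, truth)
    return np.array([
        signal.at[c, d] for c, d in zip(instances["cell_line_id"], instances["drug_id"])
    ])


@dataclass
class Benchmark:
    """A fully assembled synthetic corpus plus model-ready matrices."""

    panel: SyntheticPanel
    drugs: pd.DataFrame
    assays: pd.DataFrame
    truth: SyntheticTruth
    instances: pd.DataFrame
    X: np.ndarray                 # (n_instances, genomic_width + 3072) uint8
    y: np.ndarray
    signal: np.ndarray            # noise-free target, aligned with instances
    genomic_width: int
    genomic_fp: pd.DataFrame = field(repr=False)
    drug_fp: np.ndarray = field(repr=False)

    @property
    def ceiling(self) -> float:
        """Best achievable R^2 given the noise: Var(signal)/(Var(signal)+sd^2)."""
        v = float(np.var(self.signal))
        return v / (v + self.truth.noise_sd ** 2)


def make_benchmark(seed: int = 0, n_types: int = 5, lines_per_type: int = 40,
                   vocab_size: int = 2000, n_drugs: int = 30, n_drivers: int = 10,
                   mutation_rate: float = 0.01, noise_sd: float = 0.5) -> Benchmark:
    """Generate, curate and encode the default planted-signal benchmark."""
    ss = np.random.SeedSequence(seed).generate_state(3) % (2 ** 31)
    panel = generate_panel(n_types=n_types, lines_per_type=lines_per_type,
                           vocab_size=vocab_size, mutation_rate=mutation_rate,
                           seed=int(ss[0]), n_drivers=n_drivers)
    types = sorted(panel.cell_lines["cancer_type"].unique())
    drugs = generate_drugs(n_drugs=n_drugs, seed=int(ss[1]), indication_types=types)

    genes = sorted({g for g, _ in panel.vocab_keys})
    genc = GenomicFingerprinter(gene_whitelist=genes).fit(panel.mutations)
    G = genc.transform(panel.mutations)
    # lines with zero whitelisted mutations still need (all-zero) rows
    G = G.reindex(panel.cell_lines["cell_line_id"], fill_value=0)
    D = MolecularFingerprinter().fit().transform(drugs)

    truth = make_truth(panel, drugs, D, noise_sd=noise_sd, seed=int(ss[2]))
    assays = simulate_responses(panel, drugs, truth)

    cell_lines, _ = filter_cancer_types(panel.cell_lines, min_lines=10)
    drugs_kept, _ = filter_gdsc_drugs(drugs)
    excluded_cl = set(panel.cell_lines.cell_line_id) - set(cell_lines.cell_line_id)
    excluded_dr = set(drugs.drug_id) - set(drugs_kept.drug_id)
    instances = assemble_instances(cell_lines, drugs_kept, assays,
                                   excluded_cell_lines=excluded_cl,
                                   excluded_drugs=excluded_dr)

    ci = G.index.get_indexer(instances["cell_line_id"])
    di = pd.Index(drugs_kept["drug_id"]).get_indexer(instances["drug_id"])
    X = np.hstack([G.values[ci], D[di]]).astype(np.uint8)
    y = instances["ln_ic50"].to_numpy()
    sig = true_signal(panel, drugs_kept, truth, instances)
    return Benchmark(panel=panel, drugs=drugs_kept, assays=assays, truth=truth,
                     instances=instances, X=X, y=y, signal=sig,
                     genomic_width=G.shape[1], genomic_fp=G, drug_fp=D)
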