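"""Binary input encodings for cell lines and drugs.

Cell lines are encoded as genomic fingerprints: a fixed-order binary vector
over a (gene, genomic position) vocabulary, with 1 marking the presence of a
somatic mutation at that position and 0 its absence.  The identity of the
alternate allele is deliberately ignored: a position substituted with a
different base counts as the same feature, and insertions/deletions are not
distinguished from substitutions.

Drugs are encoded as molecular fingerprints: the concatenation of three
1,024-bit hashed substructure fingerprints (a path-based fingerprint using
bond orders, an extended circular fingerprint built on pharmacophoric
donor/acceptor/ring atom features, and a "graph only" path fingerprint that
ignores bond orders), 3,072 bits in total.

Both encoders are exposed as scikit-learn transformers so they compose with
pipelines; the module-level functions are thin wrappers over the same logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, MoleculeParseError, ParseError, UsageError

logger = logging.getLogger(__name__)

#: bits per fingerprint class and number of classes
FP_BITS_PER_CLASS = 1024
FP_N_CLASSES = 3
MOLECULAR_FP_BITS = FP_BITS_PER_CLASS * FP_N_CLASSES

MUTATION_COLUMNS = ["cell_line_id", "cancer_type", "gene", "position", "ref", "alt"]


def _as_mutation_frame(mutations) -> pd.DataFrame:
    """Validate and normalise a mutation table.

    Accepts a DataFrame with at least (cell_line_id, gene, position) columns.
    Raises :class:`ParseError` naming the offending row for malformed records.
    """
    df = pd.DataFrame(mutations)
    missing = {"cell_line_id", "gene", "position"} - set(df.columns)
    if missing:
        raise ParseError(f"mutation table lacks required columns: {sorted(missing)}")
    if len(df) == 0:
        return df
    pos = pd.to_numeric(df["position"], errors="coerce")
    bad = df.index[pos.isna() | (pos < 1)]
    if len(bad) > 0:
        raise ParseError(
            f"malformed mutation record at row {bad[0]}: "
            f"position {df.loc[bad[0], 'position']!r} is not a positive integer"
        )
    empty_gene = df.index[df["gene"].astype(str).str.len() == 0]
    if len(empty_gene) > 0:
        raise ParseError(f"malformed mutation record at row {empty_gene[0]}: empty gene")
    empty_cl = df.index[df["cell_line_id"].astype(str).str.len() == 0]
    if len(empty_cl) > 0:
        raise ParseError(f"malformed mutation record at row {empty_cl[0]}: empty cell_line_id")
    df = df.copy()
    df["position"] = pos.astype(np.int64)
    return df


@dataclass(frozen=True)
class PositionVocabulary:
    """Ordered (gene, position) feature space for genomic fingerprints.

    Order is lexicographic by gene symbol then numeric position so that
    fingerprints are reproducible across runs and machines.
    """

    keys: tuple[tuple[str, int], ...]
    index: dict[tuple[str, int], int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.keys)

    @classmethod
    def from_keys(cls, keys) -> "PositionVocabulary":
        ordered = tuple(sorted({(str(g), int(p)) for g, p in keys}))
        return cls(keys=ordered, index={k: i for i, k in enumerate(ordered)})


def build_position_vocabulary(mutations, gene_whitelist) -> PositionVocabulary:
    """Collect every distinct whitelisted (gene, position) key into a vocabulary.

    Parameters
    ----------
    mutations : table of mutation records (cell_line_id, gene, position, ...)
    gene_whitelist : iterable of gene symbols; positions in other genes are
        excluded from the feature space (the cancer-gene-census restriction).
    """
    whitelist = {str(g) for g in gene_whitelist}
    if not whitelist:
        raise ConfigurationError("gene whitelist must not be empty")
    df = _as_mutation_frame(mutations)
    if len(df) == 0:
        return PositionVocabulary.from_keys([])
    kept = df[df["gene"].astype(str).isin(whitelist)]
    return PositionVocabulary.from_keys(zip(kept["gene"], kept["position"]))


def encode_genomic_fingerprint(cell_line_mutations, vocab: PositionVocabulary) -> np.ndarray:
    """Encode one cell line's mutations as a binary vector over ``vocab``.

    A bit is 1 iff any record hits its (gene, position) key, regardless of
    ref/alt alleles or variant class; records at keys outside the vocabulary
    are ignored (their count is logged).
    """
    df = _as_mutation_frame(cell_line_mutations)
    bits = np.zeros(len(vocab), dtype=np.uint8)
    if len(df) == 0:
        return bits
    ids = df["cell_line_id"].astype(str).unique()
    if len(ids) > 1:
        raise UsageError(
            f"records span {len(ids)} cell lines ({ids[:3].tolist()}...); expected one"
        )
    n_outside = 0
    for gene, pos in zip(df["gene"].astype(str), df["position"]):
        i = vocab.index.get((gene, int(pos)))
        if i is None:
            n_outside += 1
        else:
            bits[i] = 1
    if n_outside:
        logger.info(
            "cell line %s: %d mutation record(s) outside the vocabulary ignored",
            ids[0], n_outside,
        )
    return bits


class GenomicFingerprinter(TransformerMixin, BaseEstimator):
    """Transformer from mutation tables to a binary cell-line × position matrix.

    Parameters
    ----------
    gene_whitelist : iterable of gene symbols defining the feature space,
        e.g. a cancer gene census list.

    Attributes
    ----------
    vocabulary_ : PositionVocabulary
        The ordered (gene, position) feature space learned in :meth:`fit`.
    """

    def __init__(self, gene_whitelist=()):
        self.gene_whitelist = gene_whitelist

    def fit(self, X, y=None):
        self.vocabulary_ = build_position_vocabulary(X, self.gene_whitelist)
        self.n_features_out_ = len(self.vocabulary_)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Return a 0/1 DataFrame indexed by cell_line_id, one column per key."""
        if not hasattr(self, "vocabulary_"):
            raise UsageError("GenomicFingerprinter is not fitted")
        df = _as_mutation_frame(X)
        if len(df) == 0:
            cells, rows = [], np.zeros((0, len(self.vocabulary_)), dtype=np.uint8)
        else:
            cells = sorted(df["cell_line_id"].astype(str).unique())
            rows = np.stack([
                encode_genomic_fingerprint(df[df["cell_line_id"].astype(str) == c], self.vocabulary_)
                for c in cells
            ])
        cols = [f"{g}:{p}" for g, p in self.vocabulary_.keys]
        return pd.DataFrame(rows, index=pd.Index(cells, name="cell_line_id"), columns=cols)


def _canonical_mol(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles:
        raise MoleculeParseError(str(smiles))
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(smiles)
    # round-trip through the canonical SMILES so equivalent writings of the
    # same molecule are guaranteed to hit identical generator input
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


def _fp_generators():
    make = rdFingerprintGenerator
    return (
        # class 1: path-based, bond orders respected
        make.GetRDKitFPGenerator(fpSize=FP_BITS_PER_CLASS),
        # class 2: extended — circular environments over donor/acceptor/ring
        # pharmacophoric atom features
        make.GetMorganGenerator(
            radius=2, fpSize=FP_BITS_PER_CLASS,
            atomInvariantsGenerator=make.GetMorganFeatureAtomInvGen(),
        ),
        # class 3: "graph only" — paths with bond orders ignored
        make.GetRDKitFPGenerator(fpSize=FP_BITS_PER_CLASS, useBondOrder=False),
    )


def encode_molecular_fingerprint(smiles: str) -> np.ndarray:
    """Encode a SMILES as a 3,072-bit binary vector.

    The three 1,024-bit blocks are, in order: path fingerprint with bond
    orders, feature-based circular ("extended") fingerprint, and path
    fingerprint ignoring bond orders.  The encoding is deterministic and
    invariant to SMILES rewritings of the same molecule.
    """
    mol = _canonical_mol(smiles)
    blocks = [np.asarray(g.GetFingerprint(mol), dtype=np.uint8) for g in _fp_generators()]
    return np.concatenate(blocks)


class MolecularFingerprinter(TransformerMixin, BaseEstimator):
    """Transformer from SMILES strings to a binary n_drugs × 3,072 matrix.

    Stateless (``fit`` only records the output width); ``transform`` accepts a
    sequence of SMILES or a DataFrame with a ``smiles`` column and returns a
    uint8 array of shape (n, 3072).
    """

    def fit(self, X=None, y=None):
        self.n_features_out_ = MOLECULAR_FP_BITS
        return self

    def transform(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X["smiles"].tolist()
        return np.stack([encode_molecular_fingerprint(s) for s in X]) if len(X) else \
            np.zeros((0, MOLECULAR_FP_BITS), dtype=np.uint8)


def read_smiles_file(path) -> pd.DataFrame:
    """Read .smi-style text (whitespace-separated: SMILES, then drug_id)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ParseError(f"line {ln + 1}: expected 'SMILES drug_id'")
            rows.append({"drug_id": parts[1], "smiles": parts[0]})
    return pd.DataFrame(rows, columns=["drug_id", "smiles"])


def read_mutation_table(path) -> pd.DataFrame:
    """Read a MAF-like TSV with columns cell_line_id, cancer_type, gene, position, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str}, keep_default_na=False)
    return _as_mutation_frame(df)
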