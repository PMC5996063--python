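# The five member architectures of the drug-response ensemble.
#
# Four models process the genomic and molecular fingerprints in separate
# convolutional branches whose flattened outputs are concatenated ("virtual
# docking") and mixed by a dense layer before further convolution; the
# "unified" model convolves the whole concatenated input as one entity.
# layer_count is informational (the published totals); per-layer
# hyperparameters below are this package's own defaults.
#
# Two profiles are shipped: "scaled" (narrow channels, few epochs; the
# default, sized for CPU-scale synthetic benchmarks) and "full" (wider and
# longer, for larger corpora).  Layer vocabulary:
#   {conv: {channels, kernel, stride}}  1-D convolution + ReLU
#   {pool: p}                           non-overlapping max pooling
#   {dropout: rate}                     omit rate to use the model default
#   {dense: {units, activation}}        omit activation for the model default
# A final scalar linear regression output is appended automatically.

models:
  master:
    uses_virtual_docking: true
    layer_count: 28
    dense_activation: linear
    dropout_rate: 0.10
    epochs: {full: 250, scaled: 40}
    profiles:
      scaled:
        genomic_branch:
          - {conv: {channels: 6, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 8, kernel: 6, stride: 3}}
          - {pool: 2}
        drug_branch:
          - {conv: {channels: 6, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 8, kernel: 6, stride: 3}}
          - {pool: 2}
        head:
          - {dense: {units: 160}}
          - {conv: {channels: 6, kernel: 5, stride: 1}}
          - {pool: 2}
          - {dropout: null}
      full:
        genomic_branch:
          - {conv: {channels: 32, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 32, kernel: 6, stride: 3}}
          - {pool: 2}
        drug_branch:
          - {conv: {channels: 32, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 32, kernel: 6, stride: 3}}
          - {pool: 2}
        head:
          - {dense: {units: 512}}
          - {conv: {channels: 16, kernel: 5, stride: 1}}
          - {pool: 2}
          - {dropout: null}

  fully_connected:
    uses_virtual_docking: true
    layer_count: 31
    dense_activation: linear
    dropout_rate: 0.10
    epochs: {full: 500, scaled: 60}
    profiles:
      scaled:
        genomic_branch:
          - {conv: {channels: 6, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 8, kernel: 6, stride: 3}}
          - {pool: 2}
        drug_branch:
          - {conv: {channels: 6, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 8, kernel: 6, stride: 3}}
          - {pool: 2}
        head:
          - {dense: {units: 160}}
          - {conv: {channels: 6, kernel: 5, stride: 1}}
          - {pool: 2}
          - {dropout: null}
          - {dense: {units: 64}}
          - {dropout: null}
      full:
        genomic_branch:
          - {conv: {channels: 32, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 32, kernel: 6, stride: 3}}
          - {pool: 2}
        drug_branch:
          - {conv: {channels: 32, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 32, kernel: 6, stride: 3}}
          - {pool: 2}
        head:
          - {dense: {units: 512}}
          - {conv: {channels: 16, kernel: 5, stride: 1}}
          - {pool: 2}
          - {dropout: null}
          - {dense: {units: 128}}
          - {dropout: null}

  shallow:
    uses_virtual_docking: true
    layer_count: 24
    dense_activation: linear
    dropout_rate: 0.20
    epochs: {full: 250, scaled: 30}
    profiles:
      scaled:
        genomic_branch:
          - {conv: {channels: 10, kernel: 10, stride: 4}}
          - {pool: 3}
          - {dropout: null}
        drug_branch:
          - {conv: {channels: 10, kernel: 10, stride: 4}}
          - {pool: 3}
          - {dropout: null}
        head:
          - {dense: {units: 192}}
          - {conv: {channels: 6, kernel: 5, stride: 1}}
          - {pool: 2}
          - {dropout: null}
      full:
        genomic_branch:
          - {conv: {channels: 64, kernel: 10, stride: 4}}
          - {pool: 3}
          - {dropout: null}
        drug_branch:
          - {conv: {channels: 64, kernel: 10, stride: 4}}
          - {pool: 3}
          - {dropout: null}
        head:
          - {dense: {units: 1024}}
          - {conv: {channels: 32, kernel: 5, stride: 1}}
          - {pool: 2}
          - {dropout: null}

  tanh:
    uses_virtual_docking: true
    layer_count: 31
    dense_activation: tanh
    dropout_rate: 0.15
    epochs: {full: 250, scaled: 30}
    profiles:
      scaled:
        genomic_branch:
          - {conv: {channels: 6, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 8, kernel: 6, stride: 3}}
          - {pool: 2}
        drug_branch:
          - {conv: {channels: 6, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 8, kernel: 6, stride: 3}}
          - {pool: 2}
        head:
          - {dense: {units: 160}}
          - {conv: {channels: 6, kernel: 5, stride: 1}}
          - {pool: 2}
          - {dropout: null}
          - {dense: {units: 64}}
          - {dropout: null}
      full:
        genomic_branch:
          - {conv: {channels: 32, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 32, kernel: 6, stride: 3}}
          - {pool: 2}
        drug_branch:
          - {conv: {channels: 32, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 32, kernel: 6, stride: 3}}
          - {pool: 2}
        head:
          - {dense: {units: 512}}
          - {conv: {channels: 16, kernel: 5, stride: 1}}
          - {pool: 2}
          - {dropout: null}
          - {dense: {units: 128}}
          - {dropout: null}

  unified:
    uses_virtual_docking: false
    layer_count: 17
    dense_activation: linear
    dropout_rate: 0.10
    epochs: {full: 250, scaled: 30}
    profiles:
      scaled:
        body:
          - {conv: {channels: 6, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 8, kernel: 6, stride: 3}}
          - {pool: 2}
          - {dropout: null}
          - {dense: {units: 160}}
          - {conv: {channels: 6, kernel: 5, stride: 1}}
          - {pool: 2}
      full:
        body:
          - {conv: {channels: 32, kernel: 8, stride: 8}}
          - {dropout: null}
          - {conv: {channels: 32, kernel: 6, stride: 3}}
          - {pool: 2}
          - {dropout: null}
          - {dense: {units: 512}}
          - {conv: {channels: 16, kernel: 5, stride: 1}}
          - {pool: 2}
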