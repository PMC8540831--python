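# Small end-to-end experiment on synthetic phantoms.
source: synthetic
n_per_class: 10
dataset_seed: 42
view: MLO
image_size: [256, 256]
descriptors: [iso, mlbp, iso+mlbp]
reference: iso+mlbp
selection: none
k: 5
cv_seed: 0
svm_kernels: [rbf]
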