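#!/bin/sh
# End-to-end command-line pipeline: phantom -> segment -> evaluate.
# Outputs are byte-reproducible for a fixed seed.
set -e
tmp=$(mktemp -d)

emseg phantom --shape 64,64 --classes 4 --noise 9 --seed 1 \
    --out-image "$tmp/img.nii" --out-truth "$tmp/truth.nii" \
    --sidecar "$tmp/meta.yaml"

emseg segment "$tmp/img.nii" -M 4 --seed 2 \
    --out-labels "$tmp/labels.nii" --out-params "$tmp/params.yaml" \
    --truth "$tmp/truth.nii" --out-report "$tmp/report.json"

emseg evaluate "$tmp/labels.nii" "$tmp/truth.nii" --image "$tmp/img.nii"

rm -r "$tmp"
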