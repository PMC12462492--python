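"""Clean a noisy TE alignment and score the cleaning against truth.

Builds an alignment of 20 copies of one TE family (1% divergence) flanked
by 150 bp of unrelated sequence per copy — the situation after recovering
genomic copies with generous margins — then removes gappy columns, crops
the unalignable row ends with the sliding-window operators, and scores the
result positionwise against the known noise mask.
"""

import numpy as np

from tecurate import (
    CropDivergenceParams,
    crop_end_by_divergence,
    make_noisy_msa,
    msa_cleaning_confusion,
    remove_gap_columns,
)
from tecurate.msa import GAP, Msa

msa, noise_mask = make_noisy_msa(core_length=800, n_rows=20, flank_length=150, seed=11)
print(f"alignment: {msa.n_rows} rows x {msa.width} columns "
      f"({int(noise_mask.sum())} noise positions)")

cleaned, removed = remove_gap_columns(msa)
print(f"gap-column pass removed {len(removed)} columns (this alignment has no indels)")

cropped, cropped_counts = crop_end_by_divergence(msa, CropDivergenceParams())
print(f"divergence cropper gapped {int(cropped_counts.sum())} terminal positions "
      f"(mean {cropped_counts.mean():.0f} per row; true noise is 300 per row)")

# a perfect cleaning converts exactly the flank positions to gaps
reference = Msa(list(msa.ids), np.where(noise_mask, GAP, msa.matrix))
counts, metrics = msa_cleaning_confusion(msa, reference, cropped)
print(f"vs truth: sensitivity {metrics.sensitivity:.3f}, "
      f"precision {metrics.precision:.3f}, F1 {metrics.f1:.3f}")
print("sensitivity = fraction of noise removed; precision = fraction of removed "
      "positions that really were noise")
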