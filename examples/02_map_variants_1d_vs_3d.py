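"""Compare 1D-window and 3D-contact mapping of high-risk SNPs.

Simulates a full study (contacts + GWAS + elements + genes), maps every
genome-wide-significant SNP both ways, and prints the per-condition medians
of the per-SNP median disease-association (DA) scores.
"""

import numpy as np

from snp3d.contacts import annotate_contacts, significant_contacts
from snp3d.genomic import ElementIndex
from snp3d.mapping import map_1d, map_3d, select_high_risk
from snp3d.simulate import (
    SimulationConfig,
    matrix_to_contacts,
    simulate_annotations,
    simulate_matrix,
)

cfg = SimulationConfig()  # 2,000 bins @ 10 kbp, 40 loops, 60 high-risk SNPs
matrix, truth = simulate_matrix(cfg, seed=1)
annotated = annotate_contacts(matrix_to_contacts(matrix), resolution=cfg.resolution)
sig = significant_contacts(annotated, 0.05)
snps, elements, genes = simulate_annotations(cfg, truth, seed=2)
index = ElementIndex(elements)

high_risk = select_high_risk(snps)  # p <= 5e-8
print(f"high-risk SNPs: {len(high_risk)} of {len(snps)}")

values = {"enh": {"1D": [], "3D": []}, "tgt": {"1D": [], "3D": []}, "tf": {"1D": [], "3D": []}}
for snp in high_risk:
    for mapping in (map_1d(snp, index, cfg.resolution, genes),
                    map_3d(snp, sig, index, cfg.resolution, genes)):
        if mapping.median_da_enhancer is not None:
            values["enh"][mapping.mode].append(mapping.median_da_enhancer)
        if mapping.median_da_targets is not None:
            values["tgt"][mapping.mode].append(mapping.median_da_targets)
        if mapping.tf_fraction is not None:
            values["tf"][mapping.mode].append(mapping.tf_fraction)

for label, key in (("enhancer DA", "enh"), ("target-gene DA", "tgt"),
                   ("disease-assoc. TF fraction", "tf")):
    m1 = np.median(values[key]["1D"])
    m3 = np.median(values[key]["3D"])
    print(f"{label:28s} 1D median {m1:5.2f}   3D median {m3:5.2f}")
# Elements reached through significant chromatin contacts carry higher DA
# scores than those in the SNP's linear window: the 3D route lands on the
# loop-partner fragments where the associated elements were planted, while
# the 1D window sees only the background elements flanking the variant.
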