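"""Discriminate PVR status by cosine k-means on two feature sets.

Clusters the cohort on (a) the significant imaging indices and (b) the
significant shape-mode Z-scores, and scores each matching matrix with the
Matthews correlation coefficient.
"""
import numpy as np

from bivatlas.atlas import build_atlas
from bivatlas.clustering import kmeans_cosine, match_clusters, mcc
from bivatlas.geometry import compute_imaging_indices
from bivatlas.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=0))
is_pvr = np.array([r.group == "PVR" for r in cohort.records])

idx = np.array([[compute_imaging_indices(ed, es, r).as_dict()[k]
                 for k in ("rv_ef", "lv_esvi")]
                for ed, es, r in zip(cohort.ed_surfaces, cohort.es_surfaces,
                                     cohort.records)])
atlas = build_atlas(cohort.ed_surfaces)
from bivatlas.atlas import cumulative_variance_cut, rank_modes_chi2, select_top_modes
ranking = rank_modes_chi2(atlas.zscores, is_pvr.astype(int),
                          cumulative_variance_cut(atlas))
top = select_top_modes(ranking, 3)
modes = atlas.zscores[:, top]

for name, feats in (("imaging indices (RV EF, LV ESVi)", idx),
                    (f"top-ranked shape modes {top}", modes)):
    z = (feats - feats.mean(0)) / feats.std(0, ddof=1)
    labels = kmeans_cosine(z, seed=0)
    m = match_clusters(labels, is_pvr)
    print(f"{name}: [[tp={m.tp} fn={m.fn}] [fp={m.fp} tn={m.tn}]] "
          f"MCC = {mcc(m):.3f}")
# An MCC of 0 is chance-level agreement between clusters and referral
# status; 1 would be a perfect split.
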