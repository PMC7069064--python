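"""Group comparison: integrated versus isolated chain topology.

Builds two synthetic cohorts of 30-node lollipop networks. In one cohort
the 8-node stick stays isolated; in the other every stick node gains three
connections into the clique (mirroring sensory streams integrating during
task performance). The group pipeline then runs per-node to-hitting
contrasts (Bonferroni corrected), chain-index contrasts, and the skewness
regression.
"""

import numpy as np

import lollinet as ln

N, N_STICK = 30, 8
stick = list(range(N - N_STICK, N))


def make_subject(sid: str, integrated: bool, seed: int) -> ln.SubjectResult:
    rng = np.random.default_rng(seed)
    w = ln.make_lollipop(N, N_STICK).weights.copy()
    if integrated:
        for c in stick:
            for o in rng.choice(N - N_STICK, 3, replace=False):
                w[c, o] = w[o, c] = 1.0
    w = np.clip((w + w.T) / 2 + rng.normal(0, 0.01, w.shape), 0, None)
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    res = ln.run_subject_pipeline(ln.WeightedGraph(w))
    res.subject_id, res.condition = sid, "integrated" if integrated else "isolated"
    return res


subjects = [make_subject(f"s{i}", False, 100 + i) for i in range(8)] + \
           [make_subject(f"s{i}", True, 200 + i) for i in range(8)]
out = ln.run_group_pipeline(subjects, contrast="condition", reference="isolated")

print("top nodes by |to-hitting change| (stick nodes are n22..n29):")
print(out["top_nodes"][["node", "effect", "p_adjusted", "significant"]].round(4))
print("\nskewness model:")
print(out["skewness_model"].round(3))
print("\nIntegration pulls the stick's extreme hitting times down, so the stick")
print("nodes dominate the contrast and the skewness coefficient is negative.")
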