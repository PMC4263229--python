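"""How a motif mixture encodes cross-study dependence.

With a single motif, differential states are independent across studies
and the probability of being differential everywhere factorises into the
marginals.  With two or more motifs that identity breaks: the mixture
concentrates probability on the configurations the motifs represent.
"""

import numpy as np

import cormotif as cm

one = cm.MotifModel(pi=np.array([1.0]), q=np.array([[0.5, 0.5, 0.5]]))
two = cm.MotifModel(
    pi=np.array([0.1, 0.9]),
    q=np.array([[0.9, 0.9, 0.9], [0.05, 0.05, 0.05]]),
)

for name, model in [("one motif", one), ("two motifs", two)]:
    joint = cm.joint_config_prob(model, [1, 1, 1])
    marginals = np.prod(model.pi @ model.q)
    print(f"{name}: Pr(differential in all studies) = {joint:.4f}, "
          f"product of marginals = {marginals:.4f}")

# one motif: 0.1250 = 0.1250 (independence); two motifs: 0.0730 vs 0.0025 —
# genes from the concordant motif make 'differential everywhere' about
# thirty times likelier than independence across studies would suggest.
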