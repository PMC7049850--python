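# Second reference patient: differs from the first in d, k, l, m, p, q, s, alpha, beta.
label: patient2
a: 4.31e-1
a1: 1.0e+5
b: 1.02e-9
c: 6.41e-11
c1: 0.2
d: 1.88
e: 2.08e-7
f: 4.12e-2
g: 1.25e-2
g_i: 2.0e+7
h: 2.02e+7
j: 2.49e-2
k: 5.66e+7
K_T: 9.0e-1
K_N: 6.0e-1
K_L: 6.0e-1
K_C: 6.0e-1
l: 1.81
m: 9.12
p: 3.59e-6
p_i: 1.25e-1
q: 1.59e-6
r1: 1.1e-7
r2: 6.5e-11
s: 5.12e-1
u: 3.0e-10
alpha: 5.0e+8
alpha1: 1.0e+3
alpha2: 1.0e+3
beta: 8.0e-3
beta1: 0.835
beta2: 5.4
gamma: 9.0e-1
mu1: 1.0e-1
mu_i: 10.0
delta2: 1.0e-7
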