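# First reference patient: rate/saturation constants of the tumor-immune model.
label: patient1
a: 4.31e-1        # tumor growth rate (1/day)
a1: 1.0e+5        # half-saturation of cytokine-mediated tumor kill (cells)
b: 1.02e-9        # 1/b = tumor carrying capacity (1/cell)
c: 6.41e-11       # NK-cell tumor kill rate (1/cell/day)
c1: 0.2           # maximum cytokine-mediated tumor kill rate (cell/day)
d: 2.34           # saturation level of CD8+T fractional tumor kill (1/day)
e: 2.08e-7        # fraction of circulating lymphocytes becoming NK cells (1/day)
f: 4.12e-2        # NK-cell death rate (1/day)
g: 1.25e-2        # maximum NK recruitment rate by tumor (1/day)
g_i: 2.0e+7       # steepness of CD8+T recruitment by cytokine (cell^2)
h: 2.02e+7        # steepness of NK recruitment curve (cell^2)
j: 2.49e-2        # maximum CD8+T recruitment rate (1/day)
k: 3.66e+7        # steepness of CD8+T recruitment curve (cell^2)
K_T: 9.0e-1       # fractional tumor kill by chemotherapy (1/day)
K_N: 6.0e-1       # fractional NK kill by chemotherapy (1/day)
K_L: 6.0e-1       # fractional CD8+T kill by chemotherapy (1/day)
K_C: 6.0e-1       # fractional circulating-lymphocyte kill by chemotherapy (1/day)
l: 2.09           # exponent of CD8+T fractional tumor kill (dimensionless)
m: 2.04e-1        # CD8+T death rate (1/day)
p: 3.42e-6        # NK inactivation rate by tumor (1/cell/day)
p_i: 1.25e-1      # maximum CD8+T recruitment rate by cytokine (1/day)
q: 1.42e-6        # CD8+T inactivation rate by tumor (1/cell/day)
r1: 1.1e-7        # CD8+T stimulation by NK-lysed tumor debris (1/cell/day)
r2: 6.5e-11       # CD8+T activation from circulating lymphocytes (1/cell/day)
s: 8.39e-2        # steepness of the CD8+T lysis term D (dimensionless)
u: 3.0e-10        # NK regulation of CD8+T cells (1/cell^2/day)
alpha: 7.5e+8     # constant source of circulating lymphocytes (cell/day)
alpha1: 1.0e+3    # half-saturation of CD4+T production (cells)
alpha2: 1.0e+3    # half-saturation of cytokine production (cells)
beta: 1.2e-2      # circulating-lymphocyte death/differentiation rate (1/day)
beta1: 0.835      # maximum CD4+T production rate (cell/day)
beta2: 5.4        # maximum cytokine production rate (1/cell/day)
gamma: 9.0e-1     # chemotherapy drug decay rate (1/day)
mu1: 1.0e-1       # CD4+T natural death rate (1/day)
mu_i: 10.0        # cytokine decay rate (1/day)
delta2: 1.0e-7    # CD4+T loss from tumor interaction (1/cell/day)
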