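# Parameter presets for the two parametrizations of the analytical model.
# All values are in reduced units: energies in |eps_HB|, lengths in r_HB.
#
# Known corrections applied relative to the published parameter table
# (logged when a preset is loaded):
#   * q is 2*pi/3 (the inter-arm angle is 120 degrees).
#   * real-rose eps_c is -0.2 (the table cell is corrupted).

["MB-rose"]
eps_HB = 1.0
eps_LJ = 0.1
k_s = 16.0
eps_c = -0.05
r_HB = 1.0
x_v = 1.0
sigma_LJ = 0.7
a = 0.06
C = 0.5
m_1 = 1.0
m_3 = 0.03675
q = 2.0943951023931953  # 2*pi/3
A = 0.65
k_HB = 32.0             # 2*k_s
k_LJ = 10.0
k_0 = 0.001

["real-rose"]
eps_HB = 1.0
eps_LJ = 0.2
k_s = 6.0
eps_c = -0.2
r_HB = 1.0
x_v = 1.15
sigma_LJ = 0.891
a = 0.06
C = 0.4
m_1 = 1.0
m_3 = 0.03675
q = 2.0943951023931953
A = 0.475
k_HB = 12.0
k_LJ = 16.0
k_0 = 0.001
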