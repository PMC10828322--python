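"""Embedded positron/photon interaction data for the detector materials.

Mass collision stopping powers (MeV cm^2/g) were tabulated once from the
Berger-Seltzer positron collision formula (ICRU report 37 form) with the
Sternheimer density-effect parameterization, using standard composition
constants (Z/A, mean excitation energy I, Sternheimer coefficients) for
liquid water, polystyrene and dry air. 511 keV mass attenuation
coefficients are incoherent-scattering values for low-Z media (photoelectric
and pair production are negligible there at 511 keV). Radiation lengths X0
are the standard values used by the Highland multiple-scattering formula.
"""

import numpy as np

# kinetic energy grid, keV (log-spaced 10 keV .. 3 MeV)
ENERGY_GRID_KEV = np.array([
    10.000000, 10.997282, 12.094021, 13.300135, 14.626534, 16.085211,
    17.689360, 19.453488, 21.393549, 23.527089, 25.873402, 28.453710,
    31.291346, 34.411976, 37.843819, 41.617915, 45.768393, 50.332792,
    55.352390, 60.872583, 66.943295, 73.619428, 80.961360, 89.035489,
    97.914836, 107.679705, 118.418406, 130.228058, 143.215465, 157.498083,
    173.205081, 190.478508, 209.474584, 230.365103, 253.338996, 278.604033,
    306.388706, 336.944295, 370.547136, 407.501128, 448.140475, 492.832709,
    541.982019, 596.032900, 655.474177, 720.843424, 792.731828, 871.789531,
    958.731516, 1054.344066, 1159.491882, 1275.125898, 1402.291885, 1542.139904,
    1695.934712, 1865.067196, 2051.066955, 2255.616132, 2480.564626, 2727.946825,
    3000.000000,
])

# positron mass collision stopping power, MeV cm^2/g: water
STOPPING_WATER = np.array([
    24.831999, 23.014927, 21.329680, 19.767409, 18.319786, 16.978985,
    15.737658, 14.588914, 13.526296, 12.543760, 11.635650, 10.796685,
    10.021930, 9.306780, 8.646943, 8.038419, 7.477483, 6.960668,
    6.484752, 6.046739, 5.643846, 5.273489, 4.933274, 4.620977,
    4.334539, 4.072054, 3.831754, 3.612005, 3.411297, 3.228230,
    3.061511, 2.909947, 2.772431, 2.647943, 2.535538, 2.434342,
    2.343545, 2.262398, 2.190204, 2.126316, 2.070133, 2.021094,
    1.976220, 1.935619, 1.900579, 1.870646, 1.845392, 1.824413,
    1.807328, 1.793779, 1.783429, 1.775959, 1.771074, 1.768495,
    1.767964, 1.769241, 1.772104, 1.776350, 1.781793, 1.788262,
    1.795604,
])

# positron mass collision stopping power, MeV cm^2/g: polystyrene
STOPPING_POLYSTYRENE = np.array([
    24.434314, 22.640663, 20.977747, 19.436718, 18.009260, 16.687563,
    15.464301, 14.332613, 13.286070, 12.318663, 11.424773, 10.599153,
    9.836907, 9.133467, 8.484580, 7.886282, 7.334885, 6.826958,
    6.359314, 5.928990, 5.533236, 5.169501, 4.835418, 4.528793,
    4.247594, 3.989940, 3.754090, 3.538432, 3.341475, 3.161844,
    2.998264, 2.849559, 2.714640, 2.592504, 2.482220, 2.382929,
    2.293834, 2.214198, 2.143338, 2.079326, 2.020564, 1.968717,
    1.923251, 1.883666, 1.849492, 1.820285, 1.795628, 1.775129,
    1.758415, 1.745137, 1.734967, 1.727596, 1.722733, 1.720109,
    1.719472, 1.720587, 1.723239, 1.727229, 1.732375, 1.738513,
    1.745493,
])

# positron mass collision stopping power, MeV cm^2/g: air
STOPPING_AIR = np.array([
    21.793726, 20.206994, 18.734516, 17.368724, 16.102483, 14.929077,
    13.842190, 12.835893, 11.904619, 11.043153, 10.246612, 9.510425,
    8.830320, 8.202308, 7.622665, 7.087918, 6.594830, 6.140387,
    5.721783, 5.336410, 4.981842, 4.655827, 4.356273, 4.081240,
    3.828930, 3.597673, 3.385927, 3.192260, 3.015349, 2.853970,
    2.706990, 2.573360, 2.452112, 2.342351, 2.243246, 2.154030,
    2.073992, 2.002474, 1.938863, 1.882590, 1.833126, 1.789978,
    1.752682, 1.720809, 1.693952, 1.671731, 1.653789, 1.639788,
    1.629412, 1.622360, 1.618353, 1.617124, 1.618426, 1.622025,
    1.627703, 1.635259, 1.644502, 1.655260, 1.667371, 1.680688,
    1.695077,
])

# density g/cm^3, 511 keV mass attenuation cm^2/g (incoherent), X0 g/cm^2
DENSITY = {'water': 1.000, 'polystyrene': 1.060, 'air': 1.20479e-3, 'bone': 1.850}
MU_RHO_511 = {'water': 0.0959, 'polystyrene': 0.0929, 'air': 0.0863, 'bone': 0.0959}
X0_G_CM2 = {'water': 36.08, 'polystyrene': 43.79, 'air': 36.62, 'bone': 36.08}
COMPTON_FRACTION_511 = {'water': 0.998, 'polystyrene': 0.999, 'air': 0.998, 'bone': 0.998}
# Wentzel (screened-Rutherford) hard elastic scattering: linear rate constant
# K = 2*pi*r_e^2 * sum_i n_i Z_i (Z_i + 1), per mm, and effective Z for the
# Moliere screening parameter.
HARD_SCATTER_K_MM = {'water': 0.126758, 'polystyrene': 0.107642, 'air': 1.51222e-4, 'bone': 0.234502}
Z_EFF = {'water': 7.42, 'polystyrene': 5.74, 'air': 7.22, 'bone': 7.42}
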