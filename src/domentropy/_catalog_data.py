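"""Frozen benzenoid catalog: 29 hydrogen-suppressed skeletons.

Edge lists were generated once from the ring-fusion recipes recorded in
each entry (see graph_core.build_from_rings) and are frozen here.  Every
structure was verified against the tabulated Hückel pi-electronic energy,
which distinguishes all isomers in the catalog.  Naphthalene's vertex
numbering follows the conventional two-hexagon labeling (shared edge
v2-v3) used by the worked example in the docs.
"""

ENTRIES = {
    'BH1': {
        'name': 'benzene',
        'rings': 1, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': []},
        'huckel_pe': 8.0,
        'n': 6, 'm': 6,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (4, 5)],
    },
    'BH2': {
        'name': 'naphthalene',
        'rings': 2, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [1]},
        'huckel_pe': 13.6832,
        'n': 10, 'm': 11,
        'edges': [(0, 1), (0, 5), (1, 2), (1, 6), (2, 3), (2, 9), (3, 4), (4, 5), (6, 7), (7, 8), (8, 9)],
    },
    'BH3': {
        'name': 'anthracene',
        'rings': 3, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 3]},
        'huckel_pe': 19.3137,
        'n': 14, 'm': 16,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (7, 8), (7, 10), (8, 9), (8, 13), (10, 11), (11, 12), (12, 13)],
    },
    'BH4': {
        'name': 'phenanthrene',
        'rings': 3, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 2]},
        'huckel_pe': 19.4483,
        'n': 14, 'm': 16,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (6, 10), (7, 8), (7, 13), (8, 9), (10, 11), (11, 12), (12, 13)],
    },
    'BH5': {
        'name': 'tetracene',
        'rings': 4, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 3, 3]},
        'huckel_pe': 24.9308,
        'n': 18, 'm': 21,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (7, 8), (7, 10), (8, 9), (8, 13), (10, 11), (11, 12), (11, 14), (12, 13), (12, 17), (14, 15), (15, 16), (16, 17)],
    },
    'BH6': {
        'name': 'benzo[c]phenanthrene',
        'rings': 4, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 2, 2]},
        'huckel_pe': 25.1875,
        'n': 18, 'm': 21,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (6, 10), (7, 8), (7, 13), (8, 9), (10, 11), (10, 14), (11, 12), (11, 17), (12, 13), (14, 15), (15, 16), (16, 17)],
    },
    'BH7': {
        'name': 'benzo[a]anthracene',
        'rings': 4, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 3, 2]},
        'huckel_pe': 25.1012,
        'n': 18, 'm': 21,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (7, 8), (7, 10), (8, 9), (8, 13), (10, 11), (10, 14), (11, 12), (11, 17), (12, 13), (14, 15), (15, 16), (16, 17)],
    },
    'BH8': {
        'name': 'chrysene',
        'rings': 4, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 2, 4]},
        'huckel_pe': 25.1922,
        'n': 18, 'm': 21,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (6, 10), (7, 8), (7, 13), (8, 9), (10, 11), (11, 12), (12, 13), (12, 14), (13, 17), (14, 15), (15, 16), (16, 17)],
    },
    'BH9': {
        'name': 'triphenylene',
        'rings': 4, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [0, 2, 4], 'parents': [0, 0, 0]},
        'huckel_pe': 25.2745,
        'n': 18, 'm': 21,
        'edges': [(0, 1), (0, 5), (0, 6), (1, 2), (1, 9), (2, 3), (2, 10), (3, 4), (3, 13), (4, 5), (4, 14), (5, 17), (6, 7), (7, 8), (8, 9), (10, 11), (11, 12), (12, 13), (14, 15), (15, 16), (16, 17)],
    },
    'BH10': {
        'name': 'pyrene',
        'rings': 5, 'cls': 'pericondensed',
        'recipe': {'kind': 'lattice', 'arg': [(0, 0), (1, 0), (0, 1), (1, -1)]},
        'huckel_pe': 22.5055,
        'n': 16, 'm': 19,
        'edges': [(0, 1), (0, 5), (0, 9), (1, 2), (1, 8), (2, 3), (2, 12), (3, 4), (4, 5), (5, 14), (6, 7), (6, 9), (7, 8), (8, 10), (9, 13), (10, 11), (11, 12), (13, 15), (14, 15)],
    },
    'BH11': {
        'name': 'pentacene',
        'rings': 5, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 3, 3, 3]},
        'huckel_pe': 30.544,
        'n': 22, 'm': 26,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (7, 8), (7, 10), (8, 9), (8, 13), (10, 11), (11, 12), (11, 14), (12, 13), (12, 17), (14, 15), (15, 16), (15, 18), (16, 17), (16, 21), (18, 19), (19, 20), (20, 21)],
    },
    'BH12': {
        'name': 'benzo[a]tetracene',
        'rings': 5, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 3, 3, 2]},
        'huckel_pe': 30.7255,
        'n': 22, 'm': 26,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (7, 8), (7, 10), (8, 9), (8, 13), (10, 11), (11, 12), (11, 14), (12, 13), (12, 17), (14, 15), (14, 18), (15, 16), (15, 21), (16, 17), (18, 19), (19, 20), (20, 21)],
    },
    'BH13': {
        'name': 'dibenzo[a,h]anthracene',
        'rings': 5, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 2, 3, 4]},
        'huckel_pe': 30.8805,
        'n': 22, 'm': 26,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (6, 10), (7, 8), (7, 13), (8, 9), (10, 11), (11, 12), (11, 14), (12, 13), (12, 17), (14, 15), (15, 16), (16, 17), (16, 18), (17, 21), (18, 19), (19, 20), (20, 21)],
    },
    'BH14': {
        'name': 'dibenzo[a,j]anthracene',
        'rings': 5, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 2, 3, 2]},
        'huckel_pe': 30.8795,
        'n': 22, 'm': 26,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (6, 10), (7, 8), (7, 13), (8, 9), (10, 11), (11, 12), (11, 14), (12, 13), (12, 17), (14, 15), (14, 18), (15, 16), (15, 21), (16, 17), (18, 19), (19, 20), (20, 21)],
    },
    'BH15': {
        'name': 'pentaphene',
        'rings': 5, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 3, 2, 3]},
        'huckel_pe': 30.7627,
        'n': 22, 'm': 26,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (7, 8), (7, 10), (8, 9), (8, 13), (10, 11), (10, 14), (11, 12), (11, 17), (12, 13), (14, 15), (15, 16), (15, 18), (16, 17), (16, 21), (18, 19), (19, 20), (20, 21)],
    },
    'BH16': {
        'name': 'benzo[g]chrysene',
        'rings': 5, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [0, 2, 4, 2], 'parents': [0, 0, 0, 1]},
        'huckel_pe': 30.999,
        'n': 22, 'm': 26,
        'edges': [(0, 1), (0, 5), (0, 6), (1, 2), (1, 9), (2, 3), (2, 10), (3, 4), (3, 13), (4, 5), (4, 14), (5, 17), (6, 7), (6, 18), (7, 8), (7, 21), (8, 9), (10, 11), (11, 12), (12, 13), (14, 15), (15, 16), (16, 17), (18, 19), (19, 20), (20, 21)],
    },
    'BH17': {
        'name': 'pentahelicene',
        'rings': 5, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 2, 2, 2]},
        'huckel_pe': 30.9362,
        'n': 22, 'm': 26,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (6, 10), (7, 8), (7, 13), (8, 9), (10, 11), (10, 14), (11, 12), (11, 17), (12, 13), (14, 15), (14, 18), (15, 16), (15, 21), (16, 17), (18, 19), (19, 20), (20, 21)],
    },
    'BH18': {
        'name': 'benzo[c]chrysene',
        'rings': 5, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 2, 2, 4]},
        'huckel_pe': 30.9386,
        'n': 22, 'm': 26,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (6, 10), (7, 8), (7, 13), (8, 9), (10, 11), (10, 14), (11, 12), (11, 17), (12, 13), (14, 15), (15, 16), (16, 17), (16, 18), (17, 21), (18, 19), (19, 20), (20, 21)],
    },
    'BH19': {
        'name': 'picene',
        'rings': 5, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 2, 4, 2]},
        'huckel_pe': 30.9432,
        'n': 22, 'm': 26,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (6, 10), (7, 8), (7, 13), (8, 9), (10, 11), (11, 12), (12, 13), (12, 14), (13, 17), (14, 15), (14, 18), (15, 16), (15, 21), (16, 17), (18, 19), (19, 20), (20, 21)],
    },
    'BH20': {
        'name': 'benzo[b]chrysene',
        'rings': 5, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 2, 4, 3]},
        'huckel_pe': 30.839,
        'n': 22, 'm': 26,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (6, 10), (7, 8), (7, 13), (8, 9), (10, 11), (11, 12), (12, 13), (12, 14), (13, 17), (14, 15), (15, 16), (15, 18), (16, 17), (16, 21), (18, 19), (19, 20), (20, 21)],
    },
    'BH21': {
        'name': 'dibenzo[a,c]anthracene',
        'rings': 5, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [0, 2, 4, 3], 'parents': [0, 0, 0, 1]},
        'huckel_pe': 30.9418,
        'n': 22, 'm': 26,
        'edges': [(0, 1), (0, 5), (0, 6), (1, 2), (1, 9), (2, 3), (2, 10), (3, 4), (3, 13), (4, 5), (4, 14), (5, 17), (6, 7), (7, 8), (7, 18), (8, 9), (8, 21), (10, 11), (11, 12), (12, 13), (14, 15), (15, 16), (16, 17), (18, 19), (19, 20), (20, 21)],
    },
    'BH22': {
        'name': 'dibenzo[b,g]phenanthrene',
        'rings': 5, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 2, 2, 3]},
        'huckel_pe': 30.8336,
        'n': 22, 'm': 26,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (6, 10), (7, 8), (7, 13), (8, 9), (10, 11), (10, 14), (11, 12), (11, 17), (12, 13), (14, 15), (15, 16), (15, 18), (16, 17), (16, 21), (18, 19), (19, 20), (20, 21)],
    },
    'BH23': {
        'name': 'perylene',
        'rings': 6, 'cls': 'pericondensed',
        'recipe': {'kind': 'lattice', 'arg': [(0, 0), (0, 1), (1, 0), (2, 0), (2, -1)]},
        'huckel_pe': 28.2453,
        'n': 20, 'm': 24,
        'edges': [(0, 1), (0, 5), (0, 12), (1, 2), (1, 6), (2, 3), (2, 9), (3, 4), (4, 5), (6, 7), (6, 11), (7, 8), (8, 9), (10, 11), (10, 12), (10, 16), (11, 15), (12, 18), (13, 14), (13, 16), (14, 15), (16, 17), (17, 19), (18, 19)],
    },
    'BH24': {
        'name': 'benzo[e]pyrene',
        'rings': 6, 'cls': 'pericondensed',
        'recipe': {'kind': 'lattice', 'arg': [(0, 0), (1, 0), (0, 1), (1, -1), (2, 0)]},
        'huckel_pe': 28.3361,
        'n': 20, 'm': 24,
        'edges': [(0, 1), (0, 5), (0, 9), (1, 2), (1, 8), (2, 3), (2, 12), (3, 4), (4, 5), (5, 14), (6, 7), (6, 9), (6, 19), (7, 8), (7, 18), (8, 10), (9, 13), (10, 11), (11, 12), (13, 15), (14, 15), (16, 17), (16, 19), (17, 18)],
    },
    'BH25': {
        'name': 'benzo[a]pyrene',
        'rings': 6, 'cls': 'pericondensed',
        'recipe': {'kind': 'lattice', 'arg': [(0, 0), (1, 0), (0, 1), (1, -1), (0, 2)]},
        'huckel_pe': 28.222,
        'n': 20, 'm': 24,
        'edges': [(0, 1), (0, 5), (0, 9), (1, 2), (1, 8), (2, 3), (2, 12), (3, 4), (4, 5), (5, 14), (6, 7), (6, 9), (7, 8), (8, 10), (9, 13), (10, 11), (10, 16), (11, 12), (11, 19), (13, 15), (14, 15), (16, 17), (17, 18), (18, 19)],
    },
    'BH26': {
        'name': 'hexahelicene',
        'rings': 6, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 2, 2, 2, 2]},
        'huckel_pe': 36.6814,
        'n': 26, 'm': 31,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (6, 10), (7, 8), (7, 13), (8, 9), (10, 11), (10, 14), (11, 12), (11, 17), (12, 13), (14, 15), (14, 18), (15, 16), (15, 21), (16, 17), (18, 19), (18, 22), (19, 20), (19, 25), (20, 21), (22, 23), (23, 24), (24, 25)],
    },
    'BH27': {
        'name': 'benzo[ghi]perylene',
        'rings': 7, 'cls': 'pericondensed',
        'recipe': {'kind': 'lattice', 'arg': [(0, 0), (1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1)]},
        'huckel_pe': 31.4251,
        'n': 22, 'm': 27,
        'edges': [(0, 1), (0, 5), (0, 9), (1, 2), (1, 8), (2, 3), (2, 12), (3, 4), (3, 15), (4, 5), (4, 18), (5, 19), (6, 7), (6, 9), (7, 8), (8, 10), (10, 11), (11, 12), (12, 13), (13, 14), (14, 15), (15, 16), (16, 17), (17, 18), (18, 20), (19, 21), (20, 21)],
    },
    'BH28': {
        'name': 'hexacene',
        'rings': 6, 'cls': 'catacondensed',
        'recipe': {'kind': 'chain', 'arg': [3, 3, 3, 3, 3]},
        'huckel_pe': 36.1557,
        'n': 26, 'm': 31,
        'edges': [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (3, 6), (4, 5), (4, 9), (6, 7), (7, 8), (7, 10), (8, 9), (8, 13), (10, 11), (11, 12), (11, 14), (12, 13), (12, 17), (14, 15), (15, 16), (15, 18), (16, 17), (16, 21), (18, 19), (19, 20), (19, 22), (20, 21), (20, 25), (22, 23), (23, 24), (24, 25)],
    },
    'BH29': {
        'name': 'coronene',
        'rings': 8, 'cls': 'pericondensed',
        'recipe': {'kind': 'lattice', 'arg': [(0, 0), (1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)]},
        'huckel_pe': 34.5718,
        'n': 24, 'm': 30,
        'edges': [(0, 1), (0, 5), (0, 9), (1, 2), (1, 8), (2, 3), (2, 12), (3, 4), (3, 15), (4, 5), (4, 18), (5, 19), (6, 7), (6, 9), (7, 8), (8, 10), (9, 22), (10, 11), (11, 12), (12, 13), (13, 14), (14, 15), (15, 16), (16, 17), (17, 18), (18, 20), (19, 21), (19, 23), (20, 21), (22, 23)],
    },
}
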