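"""Published reference values for serum N-glycans used as test oracles.

``SERUM_GLYCANS`` lists the 81 glycan compositions reported with a
concentration-linear MALDI response in human serum, as
(printed theoretical m/z or None for grouped isobaric rows,
 composition text, Glyconnect browser URL).  Masses are printed to one
decimal; grouped rows share the printed mass of their leading entry.

``HIGH_PRECISION_MASSES`` are the four masses reported to four decimals
for the mannose-rich hybrid and LacDiNAc classes.
"""

HIGH_PRECISION_MASSES = [
    (2383.8768, "(Hex)5 (HexNAc)1 (6NeuAc)1 + (Man)3(GlcNAc)2"),
    (2414.8714, "(Hex)5 (HexNAc)1 (Fuc)1 (GlcA)1 + (Man)3(GlcNAc)2"),
    (2474.9665, "(HexNAc)4 (Fuc)2 (6NeuAc)1 + (Man)3(GlcNAc)2"),
    (2677.0618, "(Hex)1 (HexNAc)4 (6NeuAc)2 + (Man)3(GlcNAc)2"),
]

_URL = "https://glyconnect.expasy.org/browser/compositions?f="

_RAW = """1362.5|(Hex)2 + (Man)3(GlcNAc)2|Hex:5HexNAc:2
1403.5|(Hex)1 (HexNAc)1 + (Man)3(GlcNAc)2|Hex:4HexNAc:3
1444.5|(HexNAc)2 + (Man)3(GlcNAc)2|Hex:3HexNAc:4
1524.5|(Hex)3 + (Man)3(GlcNAc)2|Hex:6HexNAc:2
1565.6|(Hex)2 (HexNAc)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:3
1590.6|(HexNAc)2 (Fuc)1 + (Man)3(GlcNAc)2|Hex:3HexNAc:4dHex:1
1606.6|(Hex)1 (HexNAc)2 + (Man)3(GlcNAc)2|Hex:4HexNAc:4
1647.6|(HexNAc)3 + (Man)3(GlcNAc)2|Hex:3HexNAc:5
1686.6|(Hex)4 + (Man)3(GlcNAc)2|Hex:7HexNAc:2
1707.6|(Hex)1 (HexNAc)1 (3-8NeuAc)1 + (Man)3(GlcNAc)2|Hex:4HexNAc:3NeuAc:1
1727.6|(Hex)3 (HexNAc)1 + (Man)3(GlcNAc)2|Hex:6HexNAc:3
1735.7|(Hex)1 (HexNAc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:4HexNAc:3NeuAc:1
1752.6|(Hex)1 (HexNAc)2 (Fuc)1 + (Man)3(GlcNAc)2|Hex:4HexNAc:4dHex:1
1768.6|(Hex)2 (HexNAc)2 + (Man)3(GlcNAc)2|Hex:5HexNAc:4
1793.7|(HexNAc)3 (Fuc)1 + (Man)3(GlcNAc)2|Hex:3HexNAc:5dHex:1
1809.7|(Hex)1 (HexNAc)3 + (Man)3(GlcNAc)2|Hex:4HexNAc:5
1848.6|(Hex)5 + (Man)3(GlcNAc)2|Hex:8HexNAc:2
1869.7|(Hex)2 (HexNAc)1 (3-8NeuAc)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:3NeuAc:1
1897.7|(Hex)2 (HexNAc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:3NeuAc:1
1914.7|(Hex)2 (HexNAc)2 (Fuc)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:4dHex:1
1938.7|(Hex)1 (HexNAc)2 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:4HexNAc:4NeuAc:1
1955.7|(Hex)1 (HexNAc)3 (Fuc)1 + (Man)3(GlcNAc)2|Hex:4HexNAc:5dHex:1
1971.7|(Hex)2 (HexNAc)3 + (Man)3(GlcNAc)2|Hex:5HexNAc:5
2010.7|(Hex)6 + (Man)3(GlcNAc)2|Hex:9HexNAc:2
|(HexNAc)3 (Fuc)1 (GlcA)1 + (Man)3(GlcNAc)2|Hex:3HexNAc:5dHex:1HexA:1
2031.7|(Hex)3 (HexNAc)1 (3-8NeuAc)1 + (Man)3(GlcNAc)2|Hex:6HexNAc:3NeuAc:1
2059.8|(Hex)3 (HexNAc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:6HexNAc:3NeuAc:1
2072.8|(Hex)2 (HexNAc)2 (3-8NeuAc)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:4NeuAc:1
2084.8|(Hex)1 (HexNAc)2 (Fuc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:4HexNAc:4dHex:1NeuAc:1
2100.8|(Hex)2 (HexNAc)2 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:4NeuAc:1
2141.8|(Hex)1 (HexNAc)3 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:4HexNAc:5NeuAc:1
2218.8|(Hex)2 (HexNAc)2 (Fuc)1 (3-8NeuAc)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:4dHex:1NeuAc:1
2246.9|(Hex)2 (HexNAc)2 (Fuc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:4dHex:1NeuAc:1
2247.8|(Hex)1 (HexNAc)3 (Fuc)3 + (Man)3(GlcNAc)2|Hex:4HexNAc:5dHex:3
2287.9|(Hex)1 (HexNAc)3 (Fuc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:4HexNAc:5dHex:1NeuAc:1
2303.9|(Hex)2 (HexNAc)3 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:5NeuAc:1
2317.9|(Hex)2 (HexNAc)2 (6NeuAc)1 (GlcA)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:4NeuAc:1HexA:1
2327.8|(Hex)4 (HexNAc)1 (Fuc)3 + (Man)3(GlcNAc)2|Hex:7HexNAc:3dHex:3
2339.9|(Hex)4 (HexNAc)1 (Fuc)1 (3-8NeuAc)1 + (Man)3(GlcNAc)2|Hex:7HexNAc:3dHex:1NeuAc:1
2376.9|(Hex)2 (HexNAc)2 (3-8NeuAc)2 + (Man)3(GlcNAc)2|Hex:5HexNAc:4NeuAc:2
2383.9|(Hex)5 (HexNAc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:8HexNAc:3NeuAc:1
2404.9|(Hex)2 (HexNAc)2 (3-8NeuAc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:4NeuAc:2
2414.9|(Hex)5 (HexNAc)1 (Fuc)1 (GlcA)1 + (Man)3(GlcNAc)2|Hex:8HexNAc:3dHex:1HexA:1
2432.9|(Hex)1 (HexNAc)5 (GlcA)1 + (Man)3(GlcNAc)2|Hex:4HexNAc:7HexA:1
|(Hex)2 (HexNAc)2 (6NeuAc)2 + (Man)3(GlcNAc)2|Hex:5HexNAc:4NeuAc:2
2439.9|(Hex)3 (HexNAc)2 (Fuc)2 (GlcA)1 + (Man)3(GlcNAc)2|Hex:6HexNAc:4dHex:2HexA:1
2465.9|(Hex)3 (HexNAc)3 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:6HexNAc:5NeuAc:1
2475.0|(HexNAc)4 (Fuc)2 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:3HexNAc:6dHex:2NeuAc:1
2491.0|(Hex)1 (HexNAc)4 (Fuc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:4HexNAc:6dHex:1NeuAc:1
2523.0|(Hex)2 (HexNAc)2 (Fuc)1 (3-8NeuAc)2 + (Man)3(GlcNAc)2|Hex:5HexNAc:4dHex:1NeuAc:2
2551.0|(Hex)2 (HexNAc)2 (Fuc)1 (3-8NeuAc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:4dHex:1NeuAc:2
2567.0|(Hex)3 (HexNAc)2 (3-8NeuAc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:6HexNAc:4NeuAc:2
2579.0|(Hex)1 (HexNAc)5 (Fuc)1 (GlcA)1 + (Man)3(GlcNAc)2|Hex:4HexNAc:7dHex:1HexA:1
|(Hex)2 (HexNAc)2 (Fuc)1 (6NeuAc)2 + (Man)3(GlcNAc)2|Hex:5HexNAc:4dHex:1NeuAc:2
2612.0|(Hex)3 (HexNAc)3 (Fuc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:6HexNAc:5dHex:1NeuAc:1
2636.0|(Hex)2 (HexNAc)3 (6NeuAc)2 + (Man)3(GlcNAc)2|Hex:5HexNAc:5NeuAc:2
2677.1|(Hex)1 (HexNAc)4 (6NeuAc)2 + (Man)3(GlcNAc)2|Hex:4HexNAc:6NeuAc:2
2693.0|(Hex)5 (HexNAc)2 (Fuc)3 + (Man)3(GlcNAc)2|Hex:8HexNAc:4dHex:3
2742.0|(Hex)3 (HexNAc)3 (3-8NeuAc)2 + (Man)3(GlcNAc)2|Hex:6HexNAc:5NeuAc:2
|(Hex)2 (HexNAc)3 (Fuc)3 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:5dHex:3NeuAc:1
2754.1|(Hex)2 (HexNAc)3 (Fuc)1 (3-8NeuAc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:5dHex:1NeuAc:2
2770.1|(Hex)3 (HexNAc)3 (3-8NeuAc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:6HexNAc:5NeuAc:2
2782.1|(Hex)2 (HexNAc)3 (Fuc)1 (6NeuAc)2 + (Man)3(GlcNAc)2|Hex:5HexNAc:5dHex:1NeuAc:2
2798.1|(Hex)3 (HexNAc)3 (6NeuAc)2 + (Man)3(GlcNAc)2|Hex:6HexNAc:5NeuAc:2
2831.1|(Hex)4 (HexNAc)4 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:7HexNAc:6NeuAc:1
|(Hex)3 (HexNAc)2 (Fuc)2 (3-8NeuAc)2 + (Man)3(GlcNAc)2|Hex:6HexNAc:4dHex:2NeuAc:2
2896.1|(Hex)5 (HexNAc)3 (Fuc)3 + (Man)3(GlcNAc)2|Hex:8HexNAc:5dHex:3
2899.1|(Hex)2 (HexNAc)5 (3-8NeuAc)1 (GlcA)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:7NeuAc:1HexA:1
2916.1|(Hex)3 (HexNAc)3 (Fuc)1 (3-8NeuAc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:6HexNAc:5dHex:1NeuAc:2
2997.1|(Hex)5 (HexNAc)2 (Fuc)3 (3-8NeuAc)1 + (Man)3(GlcNAc)2|Hex:8HexNAc:4dHex:3NeuAc:1
3045.2|(Hex)2 (HexNAc)5 (Fuc)1 (3-8NeuAc)1 (GlcA)1 + (Man)3(GlcNAc)2|Hex:5HexNAc:7dHex:1NeuAc:1HexA:1
3074.2|(Hex)3 (HexNAc)3 (3-8NeuAc)2 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:6HexNAc:5NeuAc:3
|(Hex)2 (HexNAc)3 (Fuc)3 (6NeuAc)2 + (Man)3(GlcNAc)2|Hex:5HexNAc:5dHex:3NeuAc:2
3102.2|(Hex)3 (HexNAc)3 (3-8NeuAc)1 (6NeuAc)2 + (Man)3(GlcNAc)2|Hex:6HexNAc:5NeuAc:3
3130.2|(Hex)3 (HexNAc)3 (6NeuAc)3 + (Man)3(GlcNAc)2|Hex:6HexNAc:5NeuAc:3
3135.2|(Hex)4 (HexNAc)4 (3-8NeuAc)1 (6NeuAc)1 + (Man)3(GlcNAc)2|Hex:7HexNAc:6NeuAc:2
3192.2|(Hex)3 (HexNAc)3 (Fuc)1 (3-8NeuAc)3 + (Man)3(GlcNAc)2|Hex:6HexNAc:5dHex:1NeuAc:3
3248.3|(Hex)3 (HexNAc)3 (Fuc)1 (3-8NeuAc)1 (6NeuAc)2 + (Man)3(GlcNAc)2|Hex:6HexNAc:5dHex:1NeuAc:3"""

SERUM_GLYCANS = [
    (float(m) if m else None, text, _URL + query)
    for m, text, query in (line.split("|") for line in _RAW.splitlines())
]
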