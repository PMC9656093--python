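id,name,mass,min,max,category,description
1,Hex,162.0528,0,6,neutral,Hexose
2,HexNAc,203.0793,0,5,neutral,N-acetylhexosamine
3,Fuc,146.0579,0,3,deoxyhexose,Fucose
6,3-8NeuAc,304.1270,0,4,acidic,a2-3/a2-8 NeuAc (SALSA methylamide)
7,6NeuAc,332.1583,0,4,acidic,a2-6 NeuAc (SALSA isopropylamide)
8,3-8NeuGc,320.1219,0,4,acidic,a2-3/a2-8 NeuGc (SALSA methylamide)
9,6NeuGc,348.1532,0,4,acidic,a2-6 NeuGc (SALSA isopropylamide)
14,GlcA,217.0950,0,1,acidic,Glucuronic acid (SALSA isopropylamide)
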