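# Reference partition of the head registry into 10 phenotypic modules, transcribed
# from the published module-membership table and expanded to one row per node:
# modules 1-4 are printed without side qualifiers, so each paired unit contributes
# its left and right nodes to the same module; modules 5-10 keep the printed
# left/right split. The hyoid bone (id 29) is printed under both Module 1 and
# Module 3; it is flagged ambiguous instead of being assigned.
node_id,name,module_id,ambiguous
1,Occipital,1,0
2,Parietal left,1,0
3,Parietal right,1,0
4,Temporal left,1,0
5,Temporal right,1,0
6,Sphenoid,2,0
7,Zygomatic left,5,0
8,Zygomatic right,6,0
9,Frontal,2,0
10,Ethmoidal,2,0
11,Nasal left,2,0
12,Nasal right,2,0
13,Maxilla left,5,0
14,Maxilla right,6,0
15,Lacrimal left,2,0
16,Lacrimal right,2,0
17,Palatine left,2,0
18,Palatine right,2,0
19,Nasal concha left,2,0
20,Nasal concha right,2,0
21,Vomer,2,0
22,Malleus left,1,0
23,Malleus right,1,0
24,Incus left,9,0
25,Incus right,10,0
26,Stapes left,9,0
27,Stapes right,10,0
28,Mandible,1,0
29,Hyoid bone,,1
30,Thyroid cartilage,3,0
31,Arytenoid cartilage left,3,0
32,Arytenoid cartilage right,3,0
33,Cricoid cartilage,3,0
34,Sternum,4,0
35,Clavicle left,4,0
36,Clavicle right,4,0
37,Scapula left,4,0
38,Scapula right,4,0
39,Cervical vertebra 1,4,0
40,Cervical vertebra 2,4,0
41,Cervical vertebra 3,4,0
42,Cervical vertebra 4,4,0
43,Cervical vertebra 5,4,0
44,Cervical vertebra 6,4,0
45,Cervical vertebra 7,4,0
46,Tensor tympani left,1,0
47,Tensor tympani right,1,0
48,Stapedius left,9,0
49,Stapedius right,10,0
50,Levator palpebrae superioris left,2,0
51,Levator palpebrae superioris right,2,0
52,Superior oblique left,2,0
53,Superior oblique right,2,0
54,Inferior oblique left,5,0
55,Inferior oblique right,6,0
56,Superior rectus left,2,0
57,Superior rectus right,2,0
58,Inferior rectus left,2,0
59,Inferior rectus right,2,0
60,Medial rectus left,2,0
61,Medial rectus right,2,0
62,Lateral rectus lefts,2,0
63,Lateral rectus right,2,0
64,Platsma left,5,0
65,Platsma right,6,0
66,Occipitalis left,2,0
67,Occipitalis right,2,0
68,Auricularis posterior left,1,0
69,Auricularis posterior right,1,0
70,Risorius left,5,0
71,Risorius right,6,0
72,Zygomaticus major left,5,0
73,Zygomaticus major right,6,0
74,Zygomaticus minor left,5,0
75,Zygomaticus minor right,6,0
76,Frontalis left,2,0
77,Frontalis right,2,0
78,Temporoparietalis left,7,0
79,Temporoparietalis right,8,0
80,Auricularis anterior left,7,0
81,Auricularis anterior right,8,0
82,Auricularis superior left,7,0
83,Auricularis superior right,8,0
84,Orbicularis oculi left,2,0
85,Orbicularis oculi right,2,0
86,Depressor supercilii left,5,0
87,Depressor supercilii right,6,0
88,Corrugator supercilii left,2,0
89,Corrugator supercilii right,2,0
90,Levator labii superioris alaeque nasi left,5,0
91,Levator labii superioris alaeque nasi right,6,0
92,Procerus left,2,0
93,Procerus right,2,0
94,Buccinatorius left,5,0
95,Buccinatorius right,6,0
96,Levator labii superioris left,5,0
97,Levator labii superioris right,6,0
98,Nasalis left,5,0
99,Nasalis right,6,0
100,Depressor septi nasi left,5,0
101,Depressor septi nasi right,6,0
102,Levator anguli oris facialis left,5,0
103,Levator anguli oris facialis right,6,0
104,Orbicularis oris left,5,0
105,Orbicularis oris right,6,0
106,Depressor labii inferioris left,5,0
107,Depressor labii inferioris right,6,0
108,Depressor anguli oris left,5,0
109,Depressor anguli oris right,6,0
110,Mentalis left,1,0
111,Mentalis right,1,0
112,Mylohyoideus left,1,0
113,Mylohyoideus right,1,0
114,Digastricus anterior left,1,0
115,Digastricus anterior right,1,0
116,Tensor veli palatini left,2,0
117,Tensor veli palatini right,2,0
118,Masseter left,1,0
119,Masseter right,1,0
120,Temporalis (main body) left,1,0
121,Temporalis (main body) right,1,0
122,Pterygoideus lateralis (pars. sup.) left,1,0
123,Pterygoideus lateralis (pars. sup.) right,1,0
124,Pterygoideus lateralis (pars. inf.) left,1,0
125,Pterygoideus lateralis (pars. inf.) right,1,0
126,Pterygoideus medialis left,2,0
127,Pterygoideus medialis right,2,0
128,Stylohyoideus left,1,0
129,Stylohyoideus right,1,0
130,Digastricus posterior left,1,0
131,Digastricus posterior right,1,0
132,Stylopharyngeus left,3,0
133,Stylopharyngeus right,3,0
134,Trapezius left,4,0
135,Trapezius right,4,0
136,Sternocleidomastoideus left,4,0
137,Sternocleidomastoideus right,4,0
138,Constrictor pharyngis medius left,1,0
139,Constrictor pharyngis medius right,1,0
140,Constrictor pharyngis inferior left,3,0
141,Constrictor pharyngis inferior right,3,0
142,Cricothyroideus left,3,0
143,Cricothyroideus right,3,0
144,Constrictor pharyngis superior left,1,0
145,Constrictor pharyngis superior right,1,0
146,Palatopharyngeus left,3,0
147,Palatopharyngeus right,3,0
148,Levator veli palatini left,2,0
149,Levator veli palatini right,2,0
150,Salpingopharyngeus left,3,0
151,Salpingopharyngeus right,3,0
152,Thyroarytenoideus left,3,0
153,Thyroarytenoideus right,3,0
154,Cricoarytenoideus lateralis left,3,0
155,Cricoarytenoideus lateralis right,3,0
156,Arytenoideus transversus left,3,0
157,Arytenoideus transversus right,3,0
158,Arytenoideus obliquus left,3,0
159,Arytenoideus obliquus right,3,0
160,Cricoarytenoideus posterior left,3,0
161,Cricoarytenoideus posterior right,3,0
162,Geniohyoideus left,1,0
163,Geniohyoideus right,1,0
164,Genioglossus left,1,0
165,Genioglossus right,1,0
166,Hyoglossus left,1,0
167,Hyoglossus right,1,0
168,Styloglossus left,1,0
169,Styloglossus right,1,0
170,Palatoglossus left,2,0
171,Palatoglossus right,2,0
172,Sternohyoideus left,4,0
173,Sternohyoideus right,4,0
174,Omohyoideus (pars. sup.) left,4,0
175,Omohyoideus (pars. sup.) right,4,0
176,Omohyoideus (pars. inf.) left,4,0
177,Omohyoideus (pars. inf.) right,4,0
178,Sternothryroideus left,4,0
179,Sternothryroideus right,4,0
180,Thyrohyoideus left,3,0
181,Thyrohyoideus right,3,0
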