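[
 [["Sharpness", 2, 5], ["AutoContrast", null, 4]],
 [["Equalize", null, 9], ["TranslateY", 4, 7]],
 [["Rotate", 3, 5], ["Posterize", 9, 4]],
 [["Sharpness", 8, 8], ["Invert", null, 3]],
 [["Contrast", 8, 4], ["TranslateY", 3, 8]],
 [["Brightness", 4, 7], ["Equalize", null, 2]],
 [["ShearX", 1, 2], ["Posterize", 3, 9]],
 [["Solarize", 2, 7], ["Sharpness", 7, 2]],
 [["AutoContrast", null, 4], ["HorizontalFlip", null, 4]],
 [["TranslateY", 4, 7], ["Sharpness", 2, 8]],
 [["Solarize", 7, 2], ["Brightness", 2, 6]],
 [["Invert", null, 8], ["Solarize", 7, 2]],
 [["Sharpness", 3, 6], ["Rotate", 8, 3]],
 [["Equalize", null, 4], ["Contrast", 8, 4]],
 [["Solarize", 7, 2], ["Brightness", 5, 2]],
 [["Equalize", null, 9], ["Contrast", 3, 6]],
 [["Sharpness", 2, 2], ["Invert", null, 7]],
 [["Contrast", 3, 3], ["Invert", null, 3]],
 [["Sharpness", 2, 9], ["TranslateY", 7, 7]],
 [["AutoContrast", null, 8], ["Posterize", 5, 2]],
 [["ShearX", 1, 10], ["Rotate", 7, 7]],
 [["Contrast", null, 3], ["Equalize", null, 2]],
 [["Equalize", null, 3], ["Sharpness", 8, 8]],
 [["TranslateY", 3, 1], ["Equalize", null, 9]],
 [["Solarize", 4, 1], ["Contrast", 2, 5]]
]
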