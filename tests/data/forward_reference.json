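{"network_seed": 42, "input_seed": 7, "side": 16, "bleb_channel": [[0.46432067, 0.41601832, 0.48006735, 0.47016811, 0.48675659, 0.42295684, 0.49350847, 0.43606582, 0.47095827, 0.42916732, 0.48622791, 0.46429242, 0.48957586, 0.4608941, 0.48126498, 0.47367202], [0.46265617, 0.50027713, 0.44869429, 0.45787155, 0.49614344, 0.56320033, 0.48079401, 0.49149495, 0.50408029, 0.48569199, 0.4661645, 0.49067579, 0.46744409, 0.52625677, 0.43373169, 0.51085766], [0.50641906, 0.47992404, 0.49495737, 0.48291782, 0.48353542, 0.43632241, 0.47829909, 0.47361633, 0.47978915, 0.40160805, 0.48680303, 0.38976686, 0.46536942, 0.42975451, 0.48437044, 0.46559885], [0.46056624, 0.44018347, 0.47317037, 0.45668677, 0.49926175, 0.49048083, 0.4340854, 0.52094017, 0.42958302, 0.5223231, 0.37373649, 0.52093647, 0.39368552, 0.52710963, 0.39151067, 0.57880869], [0.48778691, 0.48543711, 0.48763444, 0.47944209, 0.46416622, 0.41309995, 0.46179309, 0.42982364, 0.48119449, 0.37959226, 0.49217871, 0.41754539, 0.4682122, 0.37581385, 0.48006625, 0.48737333], [0.49156962, 0.42974316, 0.45447534, 0.50984575, 0.37450179, 0.48985814, 0.40096121, 0.53861731, 0.45961176, 0.48011337, 0.444607, 0.44066675, 0.37868828, 0.4887231, 0.35677081, 0.53437541], [0.49198148, 0.45062778, 0.49993304, 0.48319103, 0.46242409, 0.42398252, 0.49516591, 0.42068273, 0.49894864, 0.45789394, 0.47265169, 0.36463311, 0.49115772, 0.46877618, 0.47241044, 0.45323874], [0.49545603, 0.45589938, 0.44102291, 0.52629853, 0.40792309, 0.50558868, 0.36037962, 0.4828447, 0.40036702, 0.4960507, 0.34257341, 0.50548566, 0.39346846, 0.51405759, 0.36356848, 0.50593578], [0.48706494, 0.44672683, 0.47484824, 0.41827474, 0.48127276, 0.41185984, 0.49721868, 0.39253546, 0.48340837, 0.40031059, 0.46632604, 0.38856247, 0.49373435, 0.43952995, 0.4919963, 0.44471884], [0.45604635, 0.45238812, 0.45274024, 0.48224155, 0.39858716, 0.47503019, 0.41100299, 0.44367814, 0.36693981, 0.48662487, 0.33628254, 0.4282204, 0.40445354, 0.51836436, 0.4152822, 0.52899358], [0.4947945, 0.44283308, 0.48018734, 0.44135069, 0.46841162, 0.43376115, 0.48565922, 0.38762741, 0.47977565, 0.45019847, 0.5017322, 0.38539274, 0.49710292, 0.50257656, 0.49891833, 0.46215541], [0.46281513, 0.47352234, 0.36257439, 0.50006908, 0.37617991, 0.48229386, 0.35857769, 0.4917182, 0.42213632, 0.53842581, 0.34821759, 0.46339293, 0.43747885, 0.48835441, 0.41390637, 0.49961206], [0.4891074, 0.39873069, 0.5117633, 0.45890456, 0.51577785, 0.40921457, 0.47203535, 0.40141527, 0.49725358, 0.40093014, 0.48876279, 0.38942427, 0.4936908, 0.48157352, 0.4701084, 0.45633823], [0.47302154, 0.46554571, 0.43266689, 0.51556797, 0.42647108, 0.46047868, 0.39003829, 0.48133223, 0.3742854, 0.47031093, 0.36868035, 0.50143923, 0.36818494, 0.55833532, 0.42235738, 0.4869064], [0.47277684, 0.49704287, 0.47916602, 0.44649947, 0.48003862, 0.4319455, 0.47805881, 0.39812038, 0.48854862, 0.42806811, 0.4967744, 0.44912693, 0.49422256, 0.52170181, 0.49103019, 0.45756408], [0.45332543, 0.44898682, 0.37802898, 0.45102965, 0.44664784, 0.4409937, 0.35970938, 0.43970001, 0.40282703, 0.43034297, 0.36497698, 0.42486616, 0.43901585, 0.52014946, 0.42367892, 0.45785112]]}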